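Ccne1	G1-S
Ccne2	G1-S
Cdc6	G1-S
Cdc25a	G1-S
Pcna	G1-S
E2f1	G1-S
Mcm2	G1-S
Mcm6	G1-S
Slbp	G1-S
Rrm1	S
Rrm2	S
Cdc45	S
Gins2	S
Tyms	S
Fen1	S
Rfc4	S
Dhfr	S
Ccna2	G2
Cdk1	G2
Top2a	G2
Ccnf	G2
Bub1	G2
Cenpf	G2
Ndc80	G2
Ccnb1	G2-M
Ccnb2	G2-M
Plk1	G2-M
Aurka	G2-M
Bub1b	G2-M
Cdc20	G2-M
Cenpa	G2-M
Pttg1	M-G1
Cdkn3	M-G1
Rad21	M-G1
Gadd45a	M-G1
Cdc27	M-G1
Id2	M-G1
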