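# Methods

This note documents the statistical procedures implemented in `sigmatch`,
the assumptions behind them, the parameters that matter, and what the
synthetic validation does and does not demonstrate.

## Subpopulation matching

### Model

Two samples share a gene universe; each sample's cells carry subpopulation
labels produced upstream (clustering itself is out of scope — labels are an
input). The question is which subpopulations correspond across samples.

Counts are library-size normalized per cell, scaled by 1000 and transformed
with the inverse hyperbolic sine, v = asinh(1000·c/L). asinh is linear near
zero and logarithmic for large arguments, a standard variance-stabilizing
choice for UMI counts; it maps 0 to 0 and preserves within-cell rank order.
A literal forward-sinh mode exists behind `literal_sinh=True` for fidelity
experiments only: sinh of normalized values up to the scale factor
overflows double precision and destroys variance stabilization, so it is
never the default.

Per sample, each gene is tested per subpopulation against the remaining
cells with Welch's unpaired t-test; the "fold change" is the arithmetic
difference of transformed group means (a difference of asinh values is
approximately a log fold change at high expression). Discretization at the
raw threshold p < 0.001 (no multiple-testing correction — the permutation
stage, not the per-gene test, carries the inferential burden) gives the
ternary signature: +1 / −1 / 0 per gene. A zero fold change never emits a
sign, even if p < alpha (possible only under pathological ties). Degenerate
Welch inputs (both group variances zero) use the convention p = 1 for equal
means and p = 0 otherwise.

Match counting compares signatures positionally over **all** genes,
including 0 = 0 agreements. This makes the raw count mostly a function of
signature sparsity, which is deliberate: the permutation null has exactly
the same zero baseline, so the z-score measures excess agreement only. A
`include_zero_matches=False` flag restricts counting to nonzero agreements
for sensitivity analyses.

### Null model and significance

The null randomizes one side's signature matrix (default: sample A, the
control) by permuting each gene column independently across subpopulations.
This preserves every gene's value frequencies — how many subpopulations
call it up, down, or unchanged — and breaks only the co-occurrence
structure that defines cell identity. It mirrors the frequency-preserving
default of community-matrix randomizers. Each of the 100 rounds recomputes
all pairwise match counts, and all rounds × pairs are pooled into a single
null distribution (one mean and SD shared by every pair); a per-pair null
(`null_model="per-pair"`) and a whole-matrix shuffle
(`permutation_scheme="matrix"`) are available behind flags. Significance is
one-sided: a pair matches when perm_sd > 0 and
(observed − perm_mean)/perm_sd > 4. When the permuted side is all zeros the
null is degenerate (SD = 0); the z-score is reported as undefined and
nothing is significant, rather than dividing by zero.

Defaults: `n_permutations=100`, `z_threshold=4`, `alpha=0.001`,
`permuted_side="A"`, pooled null, column permutation, seed 0 in the library
(the CLI requires an explicit seed).

### Key parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.001 | raw Welch p threshold for a signature entry |
| `scale_factor` | 1000 | library-size scaling before asinh |
| `n_permutations` | 100 | randomization rounds for the null |
| `z_threshold` | 4 | SD exceedance required for a match |

## Differential expression

The DE stage works on log-normalized values v = ln(1 + 10000·c/L) (the
convention of the clustering ecosystem whose thresholds it uses). For a
query group, genes enter the Wilcoxon rank-sum test only if detected
(nonzero) in at least `min_pct` of the group's cells **and** showing at
least `min_lfc` log fold change, where
lfc = ln(mean(expm1(v_in))+1) − ln(mean(expm1(v_out))+1) in natural-log
units (the source thresholds do not state the base; natural log follows the
same ecosystem's convention). Filtering precedes testing, and the
Bonferroni divisor is the post-filter gene count — the filters define which
genes are "tested". The canonical threshold pairs are (0.25, 0.1) for
within-sample markers and (0.50, 0.75) for cross-condition comparisons.

The rank-sum p is exact (no ties, both groups ≤ 25) or the tie- and
continuity-corrected normal approximation otherwise. An independent
enumeration oracle over all group assignments backs the exact path in the
tests.

`select_cluster_count` encodes the cluster-number rule: among candidate
labelings ordered by increasing cluster count, return the first in which
every subpopulation has at least one DE gene at adjusted p < 0.05; report
the offending subpopulations per candidate otherwise.

## Cell-cycle meta-genes

Library-size normalized expression (×1000) of each cell-cycle gene is
z-scored across cells, and each phase's meta-gene is the per-cell mean of
its genes' z-scores over the phases G1-S, S, G2, G2-M, M-G1. The gene-wise
normalization is not further specified by its source, so z-scoring is the
default and min-max scaling is available behind a flag. Genes absent from
the matrix or numerically constant after normalization are dropped with a
warning; a phase left empty is an error. Because z-scores have no natural
detection zero, dot-plot style summaries report the fraction of cells with
score > 0 (above the cohort average) — this differs from the
detected-expression convention used for raw genes and is deliberate. A
small curated table of canonical mouse phase markers ships as a default
gene list; real analyses should supply their own table.

## Clonal statistics

Sphere-forming efficiency is 100·spheres/events, printed to one decimal
with half-away-from-zero rounding; fold ratios between efficiencies are
rounded the same way (reproducing the printed 28.9% / 6.3% / 4.6×
triple). Published assays often print only the rounded percentage, so
`consistent_sphere_counts` scans all integer sphere counts for the ones
consistent with the printed value — for 619 events at 28.9% the count is
uniquely 179, and for 509 events at 6.3% uniquely 32. Replicate summaries
(budding rates) use the sample (n−1) standard deviation. Proportion tables
round to two decimals and must re-sum to 100 within 0.05.

## Synthetic data

The generator emulates the paired-sample study design: two UMI count
matrices over a shared gene universe with K subpopulations, disjoint marker
gene sets (mean × `marker_effect` within the owning subpopulation in both
samples), a condition-wide perturbation (a fraction of non-marker genes ×
`treatment_effect` in every treated cell), per-sample cell numbers that may
differ by subpopulation, and NB(mean, size) noise. Subpopulation IDs are
independently renumbered between samples so matching cannot exploit label
order. The null generator instead gives each sample its own disjoint marker
structure and no planted correspondence, calibrating the chance-match rate.

Defaults are the validation conditions used throughout: K = 4, G = 2000,
100 cells per subpopulation per sample, 50 markers per subpopulation at
8-fold effect, NB size 1. The baseline mean of 0.5 puts median library
sizes in the low thousands, typical of droplet UMI data; the treatment
shift defaults to 2-fold on 10% of genes. The NB noise model is this
package's choice — the upstream data carry no stated generative model — and
the simulator deliberately omits doublets, ambient RNA, batch effects and
gene-length bias. Passing the planted-recovery and null-calibration suites
therefore shows the algorithm is correct and calibrated under clean NB
noise with separable signals; it does not certify performance on real data
with overlapping cell states, batch structure or ambient contamination.

All randomness descends from a single seed through named substreams, so
every output is byte-reproducible; cells that draw an all-zero profile are
resampled rather than dropped, keeping cell counts exact.

## Numerical choices and edge cases

- Welch variances are clipped at 0 to absorb floating-point round-off in
  the streaming variance computation; Satterthwaite df is undefined (NaN)
  on the degenerate path.
- Signature entries require strictly p < alpha; p = alpha does not pass.
- Zero-variance detection in cell-cycle scoring uses a relative tolerance
  (SD ≤ 1e-12 · max(1, |mean|)), since a constant gene can acquire an SD of
  ~1e-14 numerically.
- Count matrices reject, rather than coerce, duplicate IDs, non-integral or
  negative entries, and zero-library cells; labels require ≥ 3 cells per
  subpopulation (the smallest group for which both sides of the Welch test
  have a variance under group-vs-rest splits).
- MatrixMarket triplets use 1-based coordinate indices on disk and 0-based
  indices internally; writers are deterministic, so write→read→write is
  byte-identical.

## Validation problem sizes

The validation suites use the default generator conditions above: three
seeds for planted-correspondence recovery, twenty independent pairs for
null calibration (a 4-SD exceedance has probability ≈ 3×10⁻⁵ per pair under
an approximately normal null, so zero significant pairs are expected), 250
cells for cell-cycle recovery, 1000 random instances for Welch-oracle
agreement and exhaustive group sizes up to 8 for the exact rank-sum
enumeration. The whole suite runs in well under a minute on one CPU.
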