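import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as st_h

from sigmatch import (
    AlgorithmError,
    ClusterLabels,
    ConfigurationError,
    SignatureMatrix,
    SubpopulationMatching,
    compute_signature,
    count_matches,
    discretize,
    generate_paired_samples,
    match_signatures,
    permute_signature,
    read_signature,
    welch_t,
    write_signature,
    SimConfig,
)

from conftest import make_labels, make_transformed


class TestWelch:
    def test_worked_example(self):
        # equal variances 2.5, SE = 1, so t = -1 at Satterthwaite df = 8
        t, p = welch_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert t == pytest.approx(-1.0)
        assert p == pytest.approx(0.3466, abs=2e-4)

    def test_agrees_with_reference_implementation(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(2, 30, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(rng.normal(), rng.uniform(0.5, 2.0), size=n2)
            if rng.random() < 0.3:  # exercise ties
                x = np.round(x)
                y = np.round(y)
            t, p = welch_t(x, y)
            ref = st.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-12, abs=1e-12)
            assert abs(p - ref.pvalue) < 1e-10

    def test_degenerate_equal_constants(self):
        t, p = welch_t([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0 and t == 0.0

    def test_degenerate_separated_constants(self):
        _, p = welch_t([0.0, 0.0, 0.0, 0.0], [5.0, 5.0, 5.0, 5.0])
        assert p == 0.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ConfigurationError):
            welch_t([1.0], [1.0, 2.0])


class TestDiscretize:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (2.0, 0.0005, 1),
            (-2.0, 0.0005, -1),
            (0.0, 0.0005, 0),  # zero fold change never emits a sign
            (2.0, 0.5, 0),
            (-2.0, 0.5, 0),
            (0.0, 0.5, 0),
        ],
    )
    def test_truth_table(self, fc, p, expected):
        assert discretize([fc], [p], alpha=0.001)[0] == expected


class TestComputeSignature:
    def _fixture(self):
        # g0 high in subpop 0, g1 high in subpop 1, g2 constant
        g0 = [5.0] * 20 + [0.0] * 20
        g1 = [0.0] * 20 + [5.0] * 20
        g2 = [1.0] * 40
        t = make_transformed(np.array([g0, g1, g2]))
        return t, make_labels([0] * 20 + [1] * 20)

    def test_constructed_rows(self):
        t, labels = self._fixture()
        sig = compute_signature(t, labels, alpha=0.001)
        assert sig.row(0).tolist() == [1, -1, 0]
        assert sig.row(1).tolist() == [-1, 1, 0]

    def test_constant_gene_zero_everywhere(self):
        t, labels = self._fixture()
        sig = compute_signature(t, labels)
        assert all(sig.values[:, 2] == 0)

    def test_alpha_zero_gives_empty_signature(self):
        t, labels = self._fixture()
        sig = compute_signature(t, labels, alpha=0.0)
        assert not sig.values.any()

    def test_single_subpopulation_rejected(self):
        t, _ = self._fixture()
        with pytest.raises(AlgorithmError):
            compute_signature(t, make_labels([0] * 40))


class TestCountMatches:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 0, -1], [1, 0, -1], 3),
            ([1, 0, -1], [-1, 0, 1], 1),  # only the 0=0 position
            ([0] * 7, [0] * 7, 7),  # zero agreements count by definition
        ],
    )
    def test_examples(self, a, b, expected):
        assert count_matches(a, b) == expected

    def test_nonzero_only_flag(self):
        assert count_matches([1, 0, -1], [1, 0, -1], include_zero=False) == 2

    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            count_matches([1, 0], [1, 0, -1])


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    pairs=st_h.lists(
        st_h.tuples(
            st_h.integers(min_value=-1, max_value=1),
            st_h.integers(min_value=-1, max_value=1),
        ),
        min_size=1,
        max_size=60,
    )
)
def test_count_matches_equals_positional_comparison(pairs):
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    assert count_matches(a, b) == sum(x == y for x, y in pairs)


class TestPermuteSignature:
    def _sig(self, rng, K=5, G=40):
        vals = rng.integers(-1, 2, size=(K, G))
        return SignatureMatrix(list(range(K)), [f"g{i}" for i in range(G)], vals)

    def test_columns_preserve_value_multisets(self, rng):
        sig = self._sig(rng)
        perm = permute_signature(sig, np.random.default_rng(0))
        for j in range(sig.n_genes):
            assert sorted(perm.values[:, j]) == sorted(sig.values[:, j])

    def test_single_row_is_identity(self):
        sig = SignatureMatrix([0], ["g0", "g1"], np.array([[1, -1]]))
        perm = permute_signature(sig, np.random.default_rng(0))
        assert (perm.values == sig.values).all()

    def test_seeded_reproducibility(self, rng):
        sig = self._sig(rng)
        a = permute_signature(sig, np.random.default_rng(42)).values
        b = permute_signature(sig, np.random.default_rng(42)).values
        assert (a == b).all()

    def test_matrix_scheme_preserves_global_multiset(self, rng):
        sig = self._sig(rng)
        perm = permute_signature(sig, np.random.default_rng(0), scheme="matrix")
        assert sorted(perm.values.ravel()) == sorted(sig.values.ravel())


def _disjoint_block_signature(K=4, G=2000, block=50):
    vals = np.zeros((K, G), dtype=np.int8)
    for k in range(K):
        vals[k, k * block : (k + 1) * block] = 1 if k % 2 == 0 else -1
    return SignatureMatrix(list(range(K)), [f"g{i}" for i in range(G)], vals)


class TestMatchSignatures:
    def test_self_match_recovers_diagonal(self):
        sig = _disjoint_block_signature()
        res = match_signatures(sig, sig, seed=1)
        assert set(res.significant_pairs()) == {(k, k) for k in range(4)}
        assert res.mapping() == {k: k for k in range(4)}

    def test_all_zero_permuted_side_has_undefined_z(self):
        zeros = SignatureMatrix([0, 1], ["g0", "g1", "g2"], np.zeros((2, 3), dtype=int))
        res = match_signatures(zeros, zeros, seed=1)
        assert res.pairs["perm_sd"].eq(0).all()
        assert res.pairs["z"].isna().all()
        assert not res.pairs["significant"].any()

    def test_gene_axis_mismatch_rejected(self):
        a = _disjoint_block_signature(G=100)
        b = SignatureMatrix([0], [f"x{i}" for i in range(100)], np.zeros((1, 100), int))
        with pytest.raises(AlgorithmError, match="gene axes"):
            match_signatures(a, b, seed=1)

    def test_invariant_to_shared_gene_reordering(self, rng):
        a = _disjoint_block_signature(G=300, block=20)
        b = SignatureMatrix(
            a.subpop_ids, a.gene_ids, np.roll(a.values, 1, axis=0)
        )
        order = rng.permutation(300)
        ar = SignatureMatrix(a.subpop_ids, [a.gene_ids[i] for i in order], a.values[:, order])
        br = SignatureMatrix(b.subpop_ids, [b.gene_ids[i] for i in order], b.values[:, order])
        res = match_signatures(a, b, seed=3)
        res_r = match_signatures(ar, br, seed=3)
        assert (res.pairs["observed"] == res_r.pairs["observed"]).all()
        assert set(res.significant_pairs()) == set(res_r.significant_pairs())

    def test_matched_gene_sets_consistent_with_counts(self):
        sig = _disjoint_block_signature(G=200, block=10)
        res = match_signatures(sig, sig, seed=2)
        for a, b in res.significant_pairs():
            row = res.pairs[(res.pairs.subpop_a == a) & (res.pairs.subpop_b == b)].iloc[0]
            genes = res.matched_genes(a, b)
            nz = res.matched_genes(a, b, nonzero_only=True)
            assert len(genes) == row.observed
            assert set(nz) <= set(genes)

    def test_per_pair_null_mode(self):
        sig = _disjoint_block_signature()
        res = match_signatures(sig, sig, null_model="per-pair", seed=4)
        # per-pair SDs differ across pairs, unlike the pooled null
        assert res.pairs["perm_sd"].nunique() > 1
        assert set(res.significant_pairs()) == {(k, k) for k in range(4)}

    def test_summary_mentions_significant_pairs(self):
        sig = _disjoint_block_signature(G=200, block=10)
        text = match_signatures(sig, sig, seed=5).summary()
        assert "significant pairs" in text
        assert "0<->0" in text


class TestModelInterface:
    def test_subpopulation_renumbering_invariance(self):
        cfg = SimConfig(
            n_subpops=3, n_genes=500, cells_per_subpop=((40, 40, 40), (40, 40, 40)),
            markers_per_subpop=25, seed=5,
        )
        a, b, truth = generate_paired_samples(cfg)
        la = ClusterLabels.from_mapping(truth.labels_a, a)
        lb = ClusterLabels.from_mapping(truth.labels_b, b)
        res = SubpopulationMatching(a, la, b, lb).fit(seed=9)
        assert set(res.significant_pairs()) == set(truth.correspondence.items())

        # renumber sample B's subpopulations; matches must follow the relabeling
        relabel = {0: 2, 1: 0, 2: 1}
        lb2 = ClusterLabels(lb.barcodes, np.array([relabel[v] for v in lb.labels]))
        res2 = SubpopulationMatching(a, la, b, lb2).fit(seed=9)
        expected = {(s, relabel[t]) for s, t in truth.correspondence.items()}
        assert set(res2.significant_pairs()) == expected

    def test_gene_axis_checked_at_construction(self):
        cfg = SimConfig(n_subpops=2, n_genes=120, cells_per_subpop=((10, 10), (10, 10)),
                        markers_per_subpop=10, seed=0)
        a, b, truth = generate_paired_samples(cfg)
        la = ClusterLabels.from_mapping(truth.labels_a, a)
        lb = ClusterLabels.from_mapping(truth.labels_b, b)
        b_renamed = type(b)(
            gene_ids=[g + "_x" for g in b.gene_ids], barcodes=b.barcodes,
            counts=b.counts, sample_id=b.sample_id,
        )
        with pytest.raises(AlgorithmError):
            SubpopulationMatching(a, la, b_renamed, lb)


class TestSignatureTSV:
    def test_round_trip(self, tmp_path, rng):
        sig = SignatureMatrix(
            [0, 1, 2], [f"g{i}" for i in range(25)],
            rng.integers(-1, 2, size=(3, 25)), alpha=0.001, sample_id="demo",
        )
        p = tmp_path / "sig.tsv"
        write_signature(sig, p)
        back = read_signature(p)
        assert back.subpop_ids == sig.subpop_ids
        assert back.gene_ids == sig.gene_ids
        assert (back.values == sig.values).all()
        assert back.alpha == sig.alpha and back.sample_id == sig.sample_id
        write_signature(back, tmp_path / "sig2.tsv")
        assert (tmp_path / "sig.tsv").read_bytes() == (tmp_path / "sig2.tsv").read_bytes()
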