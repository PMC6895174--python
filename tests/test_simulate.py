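import numpy as np
import pytest

from sigmatch import (
    ConfigurationError,
    SimConfig,
    generate_cellcycle_sample,
    generate_null_pair,
    generate_paired_samples,
)

SMALL = dict(
    n_subpops=3,
    n_genes=400,
    cells_per_subpop=((40, 40, 40), (40, 40, 40)),
    markers_per_subpop=20,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides,match",
        [
            ({"n_subpops": 1}, "n_subpops"),
            ({"n_genes": 10}, "n_genes"),
            ({"marker_effect": 0.0}, "marker_effect"),
            ({"dispersion": -1.0}, "dispersion"),
            ({"treatment_gene_fraction": 1.5}, "treatment_gene_fraction"),
            ({"cells_per_subpop": ((-1, 40, 40), (40, 40, 40))}, "cells_per_subpop"),
            ({"cells_per_subpop": ((0, 0, 0), (40, 40, 40))}, "no cells"),
        ],
    )
    def test_invalid_configs_name_the_invariant(self, overrides, match):
        cfg = SimConfig(**{**SMALL, **overrides})
        with pytest.raises(ConfigurationError, match=match):
            cfg.validate()


class TestPairedSamples:
    def test_seed_determinism(self):
        cfg = SimConfig(**SMALL, seed=9)
        a1, b1, t1 = generate_paired_samples(cfg)
        a2, b2, t2 = generate_paired_samples(SimConfig(**SMALL, seed=9))
        assert (a1.counts != a2.counts).nnz == 0
        assert (b1.counts != b2.counts).nnz == 0
        assert t1.to_dict() == t2.to_dict()

    def test_different_seeds_differ(self):
        a1, _, _ = generate_paired_samples(SimConfig(**SMALL, seed=1))
        a2, _, _ = generate_paired_samples(SimConfig(**SMALL, seed=2))
        assert (a1.counts != a2.counts).nnz > 0

    def test_marker_genes_elevated_in_own_subpopulation(self):
        cfg = SimConfig(seed=21)  # defaults: K=4, G=2000, 100 cells, effect 8
        a, b, truth = generate_paired_samples(cfg)
        for mat, labels, markers in (
            (a, truth.labels_a, truth.markers_a),
            (b, truth.labels_b, truth.markers_b),
        ):
            dense = mat.dense()
            lab = np.array([labels[bc] for bc in mat.barcodes])
            gidx = {g: i for i, g in enumerate(mat.gene_ids)}
            for s, genes in markers.items():
                rows = [gidx[g] for g in genes]
                mean_in = dense[np.ix_(rows, lab == s)].mean(axis=1)
                mean_out = dense[np.ix_(rows, lab != s)].mean(axis=1)
                assert (mean_in > mean_out).all()

    def test_planted_effect_magnitude(self):
        # mean(in) / mean(out) converges to marker_effect; check within
        # 3 NB standard errors of the planted 8-fold at the default sizes
        cfg = SimConfig(seed=22)
        a, _, truth = generate_paired_samples(cfg)
        dense = a.dense()
        lab = np.array([truth.labels_a[bc] for bc in a.barcodes])
        gidx = {g: i for i, g in enumerate(a.gene_ids)}
        ratios = []
        for s, genes in truth.markers_a.items():
            rows = [gidx[g] for g in genes]
            ratios.append(
                dense[np.ix_(rows, lab == s)].mean() / dense[np.ix_(rows, lab != s)].mean()
            )
        mu_in = cfg.baseline_mean * cfg.marker_effect
        var_in = mu_in + mu_in**2 / cfg.dispersion
        n_in = 100 * cfg.markers_per_subpop
        se_ratio = np.sqrt(var_in / n_in) / cfg.baseline_mean
        assert np.allclose(ratios, cfg.marker_effect, atol=3 * se_ratio)

    def test_empty_treated_subpopulation_dropped_from_correspondence(self):
        cfg = SimConfig(
            n_subpops=3, n_genes=400, markers_per_subpop=20,
            cells_per_subpop=((40, 40, 40), (40, 0, 40)), seed=3,
        )
        a, b, truth = generate_paired_samples(cfg)
        assert b.n_cells == 80
        assert len(set(truth.labels_b.values())) == 2
        assert len(truth.correspondence) == 2
        # the dropped control subpopulation maps nowhere
        assert set(truth.correspondence) < set(truth.markers_a)

    def test_correspondence_is_bijection(self):
        _, _, truth = generate_paired_samples(SimConfig(**SMALL, seed=13))
        vals = list(truth.correspondence.values())
        assert len(vals) == len(set(vals)) == len(truth.correspondence) == 3

    def test_treatment_genes_disjoint_from_markers(self):
        _, _, truth = generate_paired_samples(SimConfig(**SMALL, seed=14))
        marker_union = {g for genes in truth.markers_a.values() for g in genes}
        assert not marker_union & set(truth.treated_genes)

    def test_all_cells_have_positive_library(self):
        # tiny means make all-zero draws likely; resampling must keep cell
        # numbers exact with every library > 0 (CountMatrix enforces it)
        cfg = SimConfig(
            n_subpops=2, n_genes=60, markers_per_subpop=5, baseline_mean=0.02,
            cells_per_subpop=((30, 30), (30, 30)), seed=4,
        )
        a, b, _ = generate_paired_samples(cfg)
        assert a.n_cells == b.n_cells == 60
        assert (a.library_sizes() > 0).all() and (b.library_sizes() > 0).all()


class TestNullPair:
    def test_marker_sets_disjoint_across_samples(self):
        _, _, truth = generate_null_pair(SimConfig(**SMALL, seed=6))
        ga = {g for genes in truth.markers_a.values() for g in genes}
        gb = {g for genes in truth.markers_b.values() for g in genes}
        assert ga and gb and not ga & gb

    def test_empty_correspondence(self):
        _, _, truth = generate_null_pair(SimConfig(**SMALL, seed=6))
        assert truth.correspondence == {}

    def test_determinism(self):
        a1, b1, _ = generate_null_pair(SimConfig(**SMALL, seed=8))
        a2, b2, _ = generate_null_pair(SimConfig(**SMALL, seed=8))
        assert (a1.counts != a2.counts).nnz == 0
        assert (b1.counts != b2.counts).nnz == 0

    def test_needs_room_for_disjoint_markers(self):
        cfg = SimConfig(n_subpops=4, n_genes=220, markers_per_subpop=50,
                        cells_per_subpop=((10,) * 4, (10,) * 4))
        with pytest.raises(ConfigurationError, match="disjoint"):
            generate_null_pair(cfg)


class TestCellCycleSample:
    def test_determinism(self):
        m1, p1, _ = generate_cellcycle_sample(seed=5, n_cells_per_phase=10, genes_per_phase=5)
        m2, p2, _ = generate_cellcycle_sample(seed=5, n_cells_per_phase=10, genes_per_phase=5)
        assert (m1.counts != m2.counts).nnz == 0
        assert p1 == p2

    def test_phase_labels_cover_all_cells(self):
        m, phase_of, sets = generate_cellcycle_sample(
            seed=5, n_cells_per_phase=10, genes_per_phase=5
        )
        assert set(phase_of) == set(m.barcodes)
        assert sorted(sets.categories) == sorted({v for v in phase_of.values()})

    @pytest.mark.parametrize("bad", [
        dict(n_cells_per_phase=0), dict(genes_per_phase=-1),
        dict(effect=0.0), dict(dispersion=0.0),
    ])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ConfigurationError):
            generate_cellcycle_sample(**bad)
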