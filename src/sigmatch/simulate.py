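"""Negative-binomial scRNA-seq simulator with planted structure.

Generates paired condition samples (control / treated) that emulate the
study design the matching algorithm targets: two UMI count matrices sharing
K subpopulations with subpopulation-specific marker genes, a
condition-wide expression perturbation in the treated sample, optionally
different subpopulation proportions, and negative-binomial noise.  Counts
are drawn NB(mean, size): ``size`` (the ``dispersion`` field) is the NB
shape parameter, so variance = mean + mean^2 / size.

Planted structure:

* every subpopulation owns ``markers_per_subpop`` disjoint marker genes
  whose NB mean is multiplied by ``marker_effect`` within that
  subpopulation, in BOTH samples;
* a ``treatment_gene_fraction`` of non-marker genes is additionally
  multiplied by ``treatment_effect`` in ALL cells of the treated sample;
* subpopulation IDs are independently renumbered between the samples, so
  downstream matching cannot rely on label order; the ground truth records
  the true bijection.

All randomness flows from ``config.seed`` through named substreams, so an
identical config yields byte-identical output.  Cells that draw an all-zero
profile are resampled (never dropped), keeping cell numbers exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .cellcycle import PHASES
from .errors import ConfigurationError
from .io import CountMatrix, GeneSetTable

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_paired_samples",
    "generate_null_pair",
    "generate_cellcycle_sample",
]


@dataclass
class SimConfig:
    """Parameters of the paired-sample simulator.

    ``cells_per_subpop`` is a pair of per-subpopulation integer vectors
    (control sample, treated sample), letting proportions differ between
    conditions; an entry of 0 removes that subpopulation from the sample.
    Defaults are the standard validation conditions: 4 subpopulations,
    2000 genes, 100 cells per subpopulation per sample, 50 markers at
    8-fold effect over a baseline mean of 0.5 with NB size 1.
    """

    n_subpops: int = 4
    n_genes: int = 2000
    cells_per_subpop: tuple[Sequence[int], Sequence[int]] | None = None
    markers_per_subpop: int = 50
    marker_effect: float = 8.0
    baseline_mean: float = 0.5
    dispersion: float = 1.0
    treatment_gene_fraction: float = 0.1
    treatment_effect: float = 2.0
    seed: int = 0

    def resolved_cells(self) -> tuple[np.ndarray, np.ndarray]:
        if self.cells_per_subpop is None:
            default = np.full(self.n_subpops, 100, dtype=np.int64)
            return default, default.copy()
        a, b = self.cells_per_subpop
        return (
            np.asarray(list(a), dtype=np.int64),
            np.asarray(list(b), dtype=np.int64),
        )

    def validate(self) -> None:
        if self.n_subpops < 2:
            raise ConfigurationError("SimConfig: n_subpops must be >= 2")
        if self.n_genes < self.n_subpops * self.markers_per_subpop:
            raise ConfigurationError(
                "SimConfig: n_genes must be >= n_subpops * markers_per_subpop "
                "(marker sets are pairwise disjoint)"
            )
        for name in ("markers_per_subpop",):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"SimConfig: {name} must be > 0")
        for name in ("marker_effect", "baseline_mean", "dispersion", "treatment_effect"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"SimConfig: {name} must be > 0")
        if not (0 <= self.treatment_gene_fraction < 1):
            raise ConfigurationError("SimConfig: treatment_gene_fraction must be in [0, 1)")
        a, b = self.resolved_cells()
        for label, v in (("control", a), ("treated", b)):
            if v.shape != (self.n_subpops,):
                raise ConfigurationError(
                    f"SimConfig: cells_per_subpop[{label}] must list one count per subpopulation"
                )
            if (v < 0).any():
                raise ConfigurationError(f"SimConfig: cells_per_subpop[{label}] must be >= 0")
            if v.sum() == 0:
                raise ConfigurationError(f"SimConfig: {label} sample has no cells")


@dataclass
class GroundTruth:
    """Planted structure of one simulated pair.

    ``correspondence`` maps control-sample subpopulation IDs to their
    treated-sample counterparts (a bijection on the shared subpopulations;
    empty for null pairs).  Marker tables are keyed by each sample's OWN
    subpopulation IDs.
    """

    labels_a: dict[str, int]
    labels_b: dict[str, int]
    markers_a: dict[int, list[str]]
    markers_b: dict[int, list[str]]
    treated_genes: list[str]
    correspondence: dict[int, int]

    def marker_table(self) -> list[tuple[str, int]]:
        """(gene, control-sample subpopulation) rows."""
        return [(g, s) for s, genes in self.markers_a.items() for g in genes]

    def to_dict(self) -> dict:
        return {
            "labels_a": self.labels_a,
            "labels_b": self.labels_b,
            "markers_a": {str(k): v for k, v in self.markers_a.items()},
            "markers_b": {str(k): v for k, v in self.markers_b.items()},
            "treated_genes": self.treated_genes,
            "correspondence": {str(k): v for k, v in self.correspondence.items()},
        }


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, size_param: float, n_cells: int) -> np.ndarray:
    """(genes x n_cells) NB draws at per-gene means ``mu``; no all-zero cells."""
    p = size_param / (size_param + mu)
    out = rng.negative_binomial(size_param, p[:, None], size=(mu.size, n_cells))
    # resample (not drop) cells that drew an all-zero profile
    for _ in range(1000):
        zero = np.flatnonzero(out.sum(axis=0) == 0)
        if not zero.size:
            return out
        out[:, zero] = rng.negative_binomial(size_param, p[:, None], size=(mu.size, zero.size))
    raise ConfigurationError("simulator cannot draw nonzero cells; means are too small")


def _assemble_sample(
    rng: np.random.Generator,
    gene_ids: list[str],
    mus: list[np.ndarray],
    raw_labels: list[int],
    n_cells: np.ndarray,
    size_param: float,
    sample_id: str,
) -> tuple[CountMatrix, dict[str, int], dict[int, int]]:
    """Draw one sample; returns (matrix, barcode->label, raw->final label map)."""
    # Draw per true subpopulation (fixed order, so the RNG stream does not
    # depend on the label renumbering), then lay cells out in raw-label
    # order: the final contiguous re-indexing must not undo the planted
    # permutation of subpopulation IDs.
    drawn = [
        (raw, _nb_draw(rng, mu, size_param, int(n)))
        for mu, raw, n in zip(mus, raw_labels, n_cells)
        if n > 0
    ]
    blocks, labels_raw = [], []
    for raw, block in sorted(drawn, key=lambda t: t[0]):
        blocks.append(block)
        labels_raw.extend([raw] * block.shape[1])
    counts = np.concatenate(blocks, axis=1)
    barcodes = [f"{sample_id}-{i:04d}" for i in range(counts.shape[1])]
    remap: dict[int, int] = {}
    for r in labels_raw:
        if r not in remap:
            remap[r] = len(remap)
    labels = {b: remap[r] for b, r in zip(barcodes, labels_raw)}
    matrix = CountMatrix(
        gene_ids=list(gene_ids),
        barcodes=barcodes,
        counts=sp.csr_matrix(counts),
        sample_id=sample_id,
    )
    return matrix, labels, remap


def generate_paired_samples(
    config: SimConfig,
) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Simulate a control/treated pair with a planted correspondence."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_structure, ss_a, ss_b = root.spawn(3)
    rng_s = np.random.default_rng(ss_structure)

    K, G, m = config.n_subpops, config.n_genes, config.markers_per_subpop
    gene_ids = [f"g{i:05d}" for i in range(G)]
    perm = rng_s.permutation(G)
    marker_idx = [perm[s * m : (s + 1) * m] for s in range(K)]
    n_treat = int(round(config.treatment_gene_fraction * G))
    non_marker = perm[K * m :]
    if n_treat > non_marker.size:
        raise ConfigurationError(
            "SimConfig: treatment_gene_fraction leaves too few non-marker genes"
        )
    treat_idx = non_marker[:n_treat]
    pi = rng_s.permutation(K)  # treated-sample renumbering of true subpops

    base = np.full(G, config.baseline_mean, dtype=np.float64)
    mus_a, mus_b = [], []
    for s in range(K):
        mu = base.copy()
        mu[marker_idx[s]] *= config.marker_effect
        mus_a.append(mu)
        mu_t = mu.copy()
        mu_t[treat_idx] *= config.treatment_effect
        mus_b.append(mu_t)

    n_a, n_b = config.resolved_cells()
    mat_a, labels_a, remap_a = _assemble_sample(
        np.random.default_rng(ss_a), gene_ids, mus_a, list(range(K)), n_a,
        config.dispersion, "control",
    )
    mat_b, labels_b, remap_b = _assemble_sample(
        np.random.default_rng(ss_b), gene_ids, mus_b, [int(pi[s]) for s in range(K)], n_b,
        config.dispersion, "treated",
    )

    markers_a = {
        remap_a[s]: [gene_ids[i] for i in marker_idx[s]] for s in range(K) if s in remap_a
    }
    markers_b = {
        remap_b[int(pi[s])]: [gene_ids[i] for i in marker_idx[s]]
        for s in range(K)
        if int(pi[s]) in remap_b
    }
    correspondence = {
        remap_a[s]: remap_b[int(pi[s])]
        for s in range(K)
        if s in remap_a and int(pi[s]) in remap_b
    }
    truth = GroundTruth(
        labels_a=labels_a,
        labels_b=labels_b,
        markers_a=markers_a,
        markers_b=markers_b,
        treated_genes=[gene_ids[i] for i in treat_idx],
        correspondence=correspondence,
    )
    return mat_a, mat_b, truth


def generate_null_pair(config: SimConfig) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Two independent samples with non-overlapping marker structure.

    Each sample gets its own disjoint marker gene sets and no treatment
    effect, so there is no planted correspondence (the ground-truth map is
    empty).  Used to calibrate how many matches occur by chance.
    """
    config.validate()
    K, G, m = config.n_subpops, config.n_genes, config.markers_per_subpop
    if G < 2 * K * m:
        raise ConfigurationError(
            "SimConfig: null pair needs n_genes >= 2 * n_subpops * markers_per_subpop "
            "(the two samples' marker sets must be disjoint)"
        )
    root = np.random.SeedSequence(config.seed)
    ss_structure, ss_a, ss_b = root.spawn(3)
    rng_s = np.random.default_rng(ss_structure)
    gene_ids = [f"g{i:05d}" for i in range(G)]
    perm = rng_s.permutation(G)
    base = np.full(G, config.baseline_mean, dtype=np.float64)

    samples = []
    marker_maps = []
    for which, ss, sample_id in (("a", ss_a, "null_a"), ("b", ss_b, "null_b")):
        offset = 0 if which == "a" else K * m
        marker_idx = [perm[offset + s * m : offset + (s + 1) * m] for s in range(K)]
        mus = []
        for s in range(K):
            mu = base.copy()
            mu[marker_idx[s]] *= config.marker_effect
            mus.append(mu)
        n_cells = config.resolved_cells()[0 if which == "a" else 1]
        mat, labels, remap = _assemble_sample(
            np.random.default_rng(ss), gene_ids, mus, list(range(K)), n_cells,
            config.dispersion, sample_id,
        )
        samples.append((mat, labels))
        marker_maps.append(
            {remap[s]: [gene_ids[i] for i in marker_idx[s]] for s in range(K) if s in remap}
        )

    (mat_a, labels_a), (mat_b, labels_b) = samples
    truth = GroundTruth(
        labels_a=labels_a,
        labels_b=labels_b,
        markers_a=marker_maps[0],
        markers_b=marker_maps[1],
        treated_genes=[],
        correspondence={},
    )
    return mat_a, mat_b, truth


def generate_cellcycle_sample(
    n_cells_per_phase: int = 50,
    genes_per_phase: int = 20,
    effect: float = 8.0,
    dispersion: float = 1.0,
    seed: int = 0,
    baseline_mean: float = 1.0,
    n_background_genes: int = 200,
) -> tuple[CountMatrix, dict[str, str], GeneSetTable]:
    """One sample with cells planted in the five cell-cycle phases.

    Each phase owns ``genes_per_phase`` genes whose NB mean is multiplied by
    ``effect`` in that phase's cells.  Returns the count matrix, the true
    phase label per barcode, and the matching gene-set table.
    ``effect=1`` yields a structureless null sample.
    """
    if n_cells_per_phase <= 0 or genes_per_phase <= 0 or n_background_genes < 0:
        raise ConfigurationError("generate_cellcycle_sample: sizes must be positive")
    if not (effect > 0 and dispersion > 0 and baseline_mean > 0):
        raise ConfigurationError("generate_cellcycle_sample: effects must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    phase_genes = {
        phase: [f"cc_{phase}_{i:03d}" for i in range(genes_per_phase)] for phase in PHASES
    }
    gene_ids = [g for phase in PHASES for g in phase_genes[phase]]
    gene_ids += [f"bg_{i:04d}" for i in range(n_background_genes)]
    G = len(gene_ids)

    base = np.full(G, baseline_mean, dtype=np.float64)
    blocks, phase_of_cell, barcodes = [], {}, []
    for j, phase in enumerate(PHASES):
        mu = base.copy()
        lo, hi = j * genes_per_phase, (j + 1) * genes_per_phase
        mu[lo:hi] *= effect
        block = _nb_draw(rng, mu, dispersion, n_cells_per_phase)
        blocks.append(block)
        for i in range(n_cells_per_phase):
            bc = f"cc-{j}-{i:04d}"
            barcodes.append(bc)
            phase_of_cell[bc] = phase
    counts = np.concatenate(blocks, axis=1)
    matrix = CountMatrix(
        gene_ids=gene_ids, barcodes=barcodes, counts=sp.csr_matrix(counts),
        sample_id="cellcycle",
    )
    return matrix, phase_of_cell, GeneSetTable(sets=phase_genes)
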