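"""Per-cell cell-cycle phase meta-genes.

A meta-gene is the per-cell average of gene-wise standardized, library-size
normalized expression over one phase's gene set.  The five phases scored
are G1-S, S, G2, G2-M and M-G1 (the classic synchronized-cell phase
partition).  Scoring pipeline:

1. library-size normalize each cell's counts (x1000, consistent with the
   matching transform's scale);
2. z-score each cell-cycle gene across cells (subtract mean, divide by SD);
3. average the z-scores of each phase's genes per cell.

Genes absent from the matrix or with zero variance are dropped with a
logged warning; a phase left with no usable genes is an error, never NaN.
Because meta-genes are built from z-scores there is no natural detection
zero; dot-plot style summaries therefore report the fraction of cells with
a POSITIVE score (above the cohort average).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import AlgorithmError, ConfigurationError
from .io import ClusterLabels, CountMatrix, GeneSetTable

__all__ = ["PHASES", "PhaseScores", "phase_metagenes", "phase_summary", "load_default_phase_genes"]

logger = logging.getLogger(__name__)

#: Canonical phase order.
PHASES = ("G1-S", "S", "G2", "G2-M", "M-G1")


@dataclass
class PhaseScores:
    """Cells x phases meta-gene values plus the genes each phase used."""

    barcodes: list[str]
    phases: list[str]
    scores: np.ndarray
    genes_used: dict[str, list[str]]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.barcodes, columns=self.phases)

    def argmax_phase(self) -> list[str]:
        """The highest-scoring phase per cell."""
        idx = np.argmax(self.scores, axis=1)
        return [self.phases[i] for i in idx]


def load_default_phase_genes() -> GeneSetTable:
    """Packaged default phase gene sets.

    A small curated list of canonical mouse cell-cycle phase markers
    shipped as a convenience default; supply your own table for real
    analyses of a specific organism or platform.
    """
    path = resources.files("sigmatch").joinpath("data/cellcycle_phase_genes.tsv")
    sets: dict[str, list[str]] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene, phase = line.split("\t")
        sets.setdefault(phase, []).append(gene)
    return GeneSetTable(sets=sets)


def phase_metagenes(
    matrix: CountMatrix,
    gene_sets: GeneSetTable,
    standardization: str = "zscore",
    scale_factor: float = 1000.0,
) -> PhaseScores:
    """Compute per-cell meta-gene scores for each phase gene set.

    ``standardization`` is ``"zscore"`` (default) or ``"minmax"`` (rescale
    each gene to [0, 1] across cells).
    """
    if standardization not in ("zscore", "minmax"):
        raise ConfigurationError(f"unknown standardization {standardization!r}")
    phases = [p for p in PHASES if p in gene_sets.sets]
    extra = [c for c in gene_sets.categories if c not in PHASES]
    phases += extra  # non-canonical categories score after the known phases
    if not phases:
        raise AlgorithmError("phase_metagenes: gene-set table has no categories")

    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    lib = matrix.library_sizes().astype(np.float64)

    # normalized expression for the union of requested genes only
    wanted = sorted({g for p in phases for g in gene_sets[p] if g in gene_index})
    rows = np.array([gene_index[g] for g in wanted], dtype=int)
    sub = matrix.counts[rows].toarray().astype(np.float64) if rows.size else np.zeros((0, matrix.n_cells))
    normed = scale_factor * sub / lib[None, :]

    mean = normed.mean(axis=1)
    sd = normed.std(axis=1, ddof=0)
    # relative tolerance: a numerically constant gene must not slip through
    usable = sd > 1e-12 * np.maximum(1.0, np.abs(mean))
    if standardization == "zscore":
        z = np.zeros_like(normed)
        z[usable] = (normed[usable] - mean[usable, None]) / sd[usable, None]
    else:
        lo = normed.min(axis=1)
        rng = normed.max(axis=1) - lo
        z = np.zeros_like(normed)
        z[usable] = (normed[usable] - lo[usable, None]) / rng[usable, None]
    std_of = dict(zip(wanted, z))
    usable_set = {g for g, u in zip(wanted, usable) if u}

    scores = np.zeros((matrix.n_cells, len(phases)))
    genes_used: dict[str, list[str]] = {}
    for j, phase in enumerate(phases):
        requested = gene_sets[phase]
        absent = [g for g in requested if g not in gene_index]
        flat = [g for g in requested if g in gene_index and g not in usable_set]
        if absent:
            logger.warning("phase %s: %d gene(s) absent from matrix: %s",
                           phase, len(absent), ", ".join(absent[:5]))
        if flat:
            logger.warning("phase %s: %d zero-variance gene(s) dropped: %s",
                           phase, len(flat), ", ".join(flat[:5]))
        used = [g for g in requested if g in usable_set]
        if not used:
            raise AlgorithmError(f"phase_metagenes: phase {phase!r} has no usable genes")
        genes_used[phase] = used
        scores[:, j] = np.mean([std_of[g] for g in used], axis=0)
    return PhaseScores(
        barcodes=list(matrix.barcodes), phases=phases, scores=scores, genes_used=genes_used
    )


def phase_summary(scores: PhaseScores, labels: ClusterLabels) -> pd.DataFrame:
    """Dot-plot style per-subpopulation summary.

    One row per (subpopulation, phase) with the fraction of cells scoring
    above zero and the mean of the positive scores (0 with
    ``no_positive=True`` when no cell in the subpopulation is positive).
    """
    if list(labels.barcodes) != list(scores.barcodes):
        raise AlgorithmError("phase_summary: labels do not cover the score barcodes")
    rows = []
    for k in labels.subpop_ids:
        mask = labels.mask(k)
        sub = scores.scores[mask]
        for j, phase in enumerate(scores.phases):
            vals = sub[:, j]
            pos = vals > 0
            rows.append(
                {
                    "subpopulation": k,
                    "phase": phase,
                    "n_cells": int(mask.sum()),
                    "frac_positive": float(pos.mean()),
                    "mean_positive": float(vals[pos].mean()) if pos.any() else 0.0,
                    "no_positive": bool(~pos.any()),
                }
            )
    return pd.DataFrame(rows)
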