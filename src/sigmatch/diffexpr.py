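"""Wilcoxon rank-sum differential expression with detection and fold-change
filters, Bonferroni correction, and the cluster-count selection criterion.

Genes enter the test only if they pass BOTH filters for the queried group:
detected (nonzero) in at least ``min_pct`` of the group's cells, and at
least ``min_lfc`` natural-log fold change over the comparison cells.  The
Bonferroni divisor is the number of genes actually tested after filtering.
The published threshold pairs this stage is used with are (min_pct=0.25,
min_lfc=0.1) for within-sample subpopulation markers and (0.50, 0.75) for
the cross-condition comparison.

The log fold change follows the log-normalization ecosystem's convention,

    lfc = ln(mean(expm1(v_in)) + 1) - ln(mean(expm1(v_out)) + 1)

computed on log-normalized values ``v`` (natural-log units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import AlgorithmError, ConfigurationError, SelectionError
from .io import ClusterLabels
from .transform import TransformedMatrix

__all__ = [
    "DEResult",
    "wilcoxon_rank_sum",
    "wilcoxon_exact_enumeration",
    "de_genes",
    "de_table",
    "select_cluster_count",
]

#: Largest per-group size at which the exact rank-sum distribution is used
#: (ties force the tie-corrected normal approximation at any size).
EXACT_MAX_N = 25


def wilcoxon_rank_sum(x, y) -> float:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact null distribution when both groups have at most
    :data:`EXACT_MAX_N` observations and the pooled values carry no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 1 or y.size < 1:
        raise ConfigurationError("wilcoxon_rank_sum requires non-empty groups")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and min(x.size, y.size) <= EXACT_MAX_N) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def wilcoxon_exact_enumeration(x, y) -> float:
    """Exact two-tailed rank-sum p by full enumeration of group assignments.

    Brute force over all C(n1+n2, n1) ways to assign the pooled
    (tie-free) values to the first group; intended as an independent check
    of :func:`wilcoxon_rank_sum` at small n, not for production use.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size != pooled.size:
        raise ConfigurationError("enumeration oracle requires tie-free data")
    n1 = x.size
    ranks = st.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in combinations(range(pooled.size), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    total = us.size
    p = 2.0 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / total
    return float(min(1.0, p))


@dataclass
class DEResult:
    """One gene's differential-expression record for one group."""

    gene: str
    group: int
    p_value: float
    p_adjusted: float
    log_fc: float
    pct_in: float
    pct_out: float


def _log_mean_expm1(values: np.ndarray) -> float:
    return math.log(np.expm1(values).mean() + 1.0)


def de_genes(
    transformed: TransformedMatrix,
    labels: ClusterLabels,
    group: int,
    min_pct: float = 0.25,
    min_lfc: float = 0.1,
    mode: str = "one-vs-rest",
) -> list[DEResult]:
    """Upregulated genes of ``group`` versus the comparison cells.

    ``mode="one-vs-rest"`` compares the group's cells with all remaining
    cells; ``mode="sample-vs-sample"`` requires exactly two groups (one per
    sample/condition) and is otherwise the same comparison.  Genes failing
    the detection-fraction or log-fold-change filter are excluded BEFORE
    testing; the Bonferroni divisor is the post-filter gene count.  Results
    are sorted by adjusted p, then |log_fc| descending.
    """
    if transformed.method != "lognorm":
        raise AlgorithmError("de_genes expects a lognorm-transformed matrix")
    if list(labels.barcodes) != list(transformed.barcodes):
        raise AlgorithmError("de_genes: labels do not cover the matrix barcodes")
    if group not in labels.subpop_ids:
        raise ConfigurationError(f"unknown group {group}")
    if not (0 <= min_pct <= 1):
        raise ConfigurationError("min_pct must be in [0, 1]")
    if min_lfc < 0:
        raise ConfigurationError("min_lfc must be >= 0")
    if mode not in ("one-vs-rest", "sample-vs-sample"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if mode == "sample-vs-sample" and labels.n_subpops != 2:
        raise ConfigurationError("sample-vs-sample mode requires exactly 2 groups")

    in_mask = labels.mask(group)
    out_mask = ~in_mask
    X = transformed.values.tocsr()
    n_in, n_out = int(in_mask.sum()), int(out_mask.sum())

    # detection fractions from the sparsity pattern (0 iff count 0)
    pattern = X.copy()
    pattern.data = np.ones_like(pattern.data)
    det_in = np.asarray(pattern[:, in_mask].sum(axis=1)).ravel() / n_in
    det_out = np.asarray(pattern[:, out_mask].sum(axis=1)).ravel() / n_out

    Xin = X[:, in_mask]
    Xout = X[:, out_mask]
    mean_expm1_in = np.asarray(np.expm1(Xin.todense()).mean(axis=1)).ravel()
    mean_expm1_out = np.asarray(np.expm1(Xout.todense()).mean(axis=1)).ravel()
    log_fc = np.log(mean_expm1_in + 1.0) - np.log(mean_expm1_out + 1.0)

    tested = np.flatnonzero((det_in >= min_pct) & (log_fc >= min_lfc))
    n_tested = tested.size
    results: list[DEResult] = []
    for g in tested:
        p = wilcoxon_rank_sum(
            np.asarray(Xin[g].todense()).ravel(), np.asarray(Xout[g].todense()).ravel()
        )
        results.append(
            DEResult(
                gene=transformed.gene_ids[g],
                group=group,
                p_value=p,
                p_adjusted=min(1.0, p * n_tested),
                log_fc=float(log_fc[g]),
                pct_in=float(det_in[g]),
                pct_out=float(det_out[g]),
            )
        )
    results.sort(key=lambda r: (r.p_adjusted, -abs(r.log_fc)))
    return results


def de_table(results: list[DEResult]) -> pd.DataFrame:
    """DE results as the canonical output table."""
    cols = ["gene", "group", "p_value", "p_adjusted", "log_fc", "pct_in", "pct_out"]
    return pd.DataFrame([vars(r) for r in results], columns=cols)


def select_cluster_count(
    transformed: TransformedMatrix,
    candidate_labelings: list[ClusterLabels],
    min_pct: float = 0.25,
    min_lfc: float = 0.1,
    alpha_adj: float = 0.05,
) -> ClusterLabels:
    """Pick the appropriate number of clusters.

    Returns the first candidate labeling (the list is ordered by increasing
    cluster count) in which EVERY subpopulation has at least one
    differentially expressed gene at adjusted p < ``alpha_adj``; ties on
    cluster count resolve to input order.  Raises
    :class:`~sigmatch.errors.SelectionError` listing, per candidate, the
    subpopulations lacking DE genes when none qualifies.
    """
    if not candidate_labelings:
        raise ConfigurationError("select_cluster_count requires at least one candidate")
    failures: list[str] = []
    for labeling in candidate_labelings:
        lacking = []
        for k in labeling.subpop_ids:
            res = de_genes(transformed, labeling, k, min_pct=min_pct, min_lfc=min_lfc)
            if not any(r.p_adjusted < alpha_adj for r in res):
                lacking.append(k)
        if not lacking:
            return labeling
        failures.append(f"k={labeling.n_subpops}: subpopulations without DE genes: {lacking}")
    raise SelectionError(
        "no candidate clustering has DE genes in all subpopulations; " + "; ".join(failures)
    )
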