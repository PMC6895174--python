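"""Cross-condition subpopulation matching via ternary gene signatures.

The algorithm compares cell subpopulations between two samples (e.g. a
vehicle-treated and a drug-treated sample of the same organoid line) whose
cluster labels were derived independently and therefore cannot be compared
directly:

1. Counts are library-size normalized (x1000) and asinh-transformed
   (:func:`sigmatch.transform.normalize_transform`).
2. Within each sample, every gene is tested per subpopulation against the
   remaining cells with an unpaired, unequal-variance (Welch) two-sample
   t-test; the fold change is the arithmetic difference of transformed
   means.
3. Fold changes with p below ``alpha`` (default 0.001) are discretized to
   +1 / -1 by sign; everything else becomes 0.  The rows of this
   subpopulations x genes ternary matrix are the gene signatures.
4. For every ordered pair of subpopulations across the two samples, the
   number of positions where the two signatures agree is counted over all
   genes (0 = 0 agreements included; the permutation null absorbs this
   baseline).
5. The designated sample's signature matrix is randomized (default: each
   gene column independently permuted across subpopulations, preserving
   per-gene value frequencies) ``n_permutations`` times (default 100); all
   pairwise match counts from all rounds are pooled into one null
   distribution.  A pair is a significant match when its observed count
   exceeds the null mean by more than ``z_threshold`` (default 4) null
   standard deviations.

The model/results interface is :class:`SubpopulationMatching` /
:class:`MatchResults`; the underlying operations (:func:`welch_t`,
:func:`compute_signature`, :func:`count_matches`, :func:`permute_signature`,
:func:`match_signatures`) are ordinary functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import AlgorithmError, ConfigurationError, FormatError, ValidationError
from .io import ClusterLabels, CountMatrix
from .transform import TransformedMatrix, normalize_transform

__all__ = [
    "welch_t",
    "discretize",
    "SignatureMatrix",
    "compute_signature",
    "count_matches",
    "permute_signature",
    "match_signatures",
    "MatchResults",
    "SubpopulationMatching",
    "write_signature",
    "read_signature",
]

#: Library default seed for the permutation null (the CLI requires an
#: explicit seed; programmatic callers may rely on this fixed value).
DEFAULT_SEED = 0


# ---------------------------------------------------------------------------
# Welch's t-test


def _welch_from_stats(mean1, var1, n1, mean2, var2, n2):
    """Vectorized Welch statistic, Satterthwaite df and two-tailed p.

    Degenerate convention (both sample variances zero): p = 1 when the means
    agree, p = 0 when they differ.  Arrays broadcast elementwise.
    """
    mean1, var1, mean2, var2 = (np.asarray(a, dtype=np.float64) for a in (mean1, var1, mean2, var2))
    var1 = np.maximum(var1, 0.0)  # guard tiny negative fp round-off
    var2 = np.maximum(var2, 0.0)
    se2 = var1 / n1 + var2 / n2
    diff = mean1 - mean2
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * st.t.sf(np.abs(t), df)
    inf_t = np.where(diff > 0, np.inf, np.where(diff < 0, -np.inf, 0.0))
    t = np.where(degenerate, inf_t, t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    df = np.where(degenerate, np.nan, df)
    return t, df, p


def welch_t(x, y) -> tuple[float, float]:
    """Two-sample unpaired t-test assuming unequal variances.

    Returns ``(t_statistic, p_value)`` with the two-tailed p from the t
    distribution at Welch-Satterthwaite degrees of freedom.  Requires at
    least two observations per group.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ConfigurationError("welch_t requires at least 2 observations per group")
    t, _, p = _welch_from_stats(
        x.mean(), x.var(ddof=1), x.size, y.mean(), y.var(ddof=1), y.size
    )
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Signatures


def discretize(fold_change, p_value, alpha: float = 0.001) -> np.ndarray:
    """Ternarize fold changes: sign(fc) where p < alpha and fc != 0, else 0.

    +1 marks significantly upregulated genes, -1 significantly
    downregulated genes, 0 non-significant genes.  A zero fold change is
    never emitted as +/-1 even if p < alpha (pathological ties).
    """
    fc = np.asarray(fold_change, dtype=np.float64)
    p = np.asarray(p_value, dtype=np.float64)
    return np.where((p < alpha) & (fc != 0), np.sign(fc), 0.0).astype(np.int8)


@dataclass
class SignatureMatrix:
    """Subpopulations x genes ternary matrix of discretized fold changes."""

    subpop_ids: list[int]
    gene_ids: list[str]
    values: np.ndarray
    alpha: float = 0.001
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.subpop_ids), len(self.gene_ids)):
            raise ValidationError("SignatureMatrix: shape must be subpopulations x genes")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValidationError("SignatureMatrix: entries must be in {-1, 0, 1}")
        self.values = self.values.astype(np.int8)

    @property
    def n_subpops(self) -> int:
        return len(self.subpop_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, subpop: int) -> np.ndarray:
        return self.values[self.subpop_ids.index(subpop)]

    def to_frame(self) -> pd.DataFrame:
        """Genes as rows, subpopulations as columns."""
        return pd.DataFrame(
            self.values.T, index=self.gene_ids, columns=[str(s) for s in self.subpop_ids]
        )


def compute_signature(
    transformed: TransformedMatrix, labels: ClusterLabels, alpha: float = 0.001
) -> SignatureMatrix:
    """Build the per-subpopulation ternary gene signature of one sample.

    For each (subpopulation, gene), the cells within the subpopulation are
    compared to the remaining cells in the sample by Welch's t-test on the
    transformed values; the fold change is the arithmetic difference of the
    two group means.  The sign of fold changes with p < ``alpha`` is kept,
    everything else is 0.  The raw threshold is applied without
    multiple-testing correction.
    """
    if list(labels.barcodes) != list(transformed.barcodes):
        raise ValidationError("compute_signature: labels do not cover the matrix barcodes")
    K = labels.n_subpops
    if K < 2:
        raise AlgorithmError("compute_signature: at least 2 subpopulations required")
    X = transformed.values  # genes x cells, CSR
    Xsq = X.multiply(X)
    total_sum = np.asarray(X.sum(axis=1)).ravel()
    total_sq = np.asarray(Xsq.sum(axis=1)).ravel()
    n_total = transformed.n_cells

    rows = np.zeros((K, transformed.n_genes), dtype=np.int8)
    for k in range(K):
        ind = labels.mask(k).astype(np.float64)
        n_in = int(ind.sum())
        n_out = n_total - n_in
        if n_in < 2 or n_out < 2:
            raise AlgorithmError(
                f"compute_signature: subpopulation {k} leaves a group of < 2 cells"
            )
        s_in = X @ ind
        q_in = Xsq @ ind
        s_out = total_sum - s_in
        q_out = total_sq - q_in
        mean_in = s_in / n_in
        mean_out = s_out / n_out
        var_in = (q_in - n_in * mean_in**2) / (n_in - 1)
        var_out = (q_out - n_out * mean_out**2) / (n_out - 1)
        _, _, p = _welch_from_stats(mean_in, var_in, n_in, mean_out, var_out, n_out)
        fc = mean_in - mean_out
        rows[k] = discretize(fc, p, alpha)
    return SignatureMatrix(
        subpop_ids=labels.subpop_ids,
        gene_ids=list(transformed.gene_ids),
        values=rows,
        alpha=alpha,
        sample_id=transformed.sample_id,
    )


# ---------------------------------------------------------------------------
# Match counting and the permutation null


def count_matches(row_a, row_b, *, include_zero: bool = True) -> int:
    """Number of positions where two ternary signatures agree.

    By default agreement at 0 = 0 counts as a match (matches are determined
    over all genes; the permutation null absorbs the zero-agreement
    baseline).  ``include_zero=False`` restricts to nonzero agreements.
    """
    a = np.asarray(row_a)
    b = np.asarray(row_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("count_matches: vectors must share one common length")
    eq = a == b
    if not include_zero:
        eq &= a != 0
    return int(eq.sum())


def permute_signature(
    sig: SignatureMatrix, rng: np.random.Generator, scheme: str = "columns"
) -> SignatureMatrix:
    """Randomize a signature matrix for the permutation null.

    ``scheme="columns"`` (default) independently permutes each gene column
    across subpopulations, exactly preserving every gene's value multiset —
    the frequency-preserving null of community-matrix randomizers.
    ``scheme="matrix"`` shuffles all entries of the whole matrix.
    """
    V = sig.values
    if scheme == "columns":
        keys = rng.random(V.shape)
        order = np.argsort(keys, axis=0)
        out = np.take_along_axis(V, order, axis=0)
    elif scheme == "matrix":
        flat = V.ravel().copy()
        rng.shuffle(flat)
        out = flat.reshape(V.shape)
    else:
        raise ConfigurationError(f"unknown permutation scheme {scheme!r}")
    return SignatureMatrix(
        subpop_ids=list(sig.subpop_ids),
        gene_ids=list(sig.gene_ids),
        values=out,
        alpha=sig.alpha,
        sample_id=sig.sample_id,
    )


def _pair_counts(A: np.ndarray, B: np.ndarray, include_zero: bool) -> np.ndarray:
    """KA x KB match counts between the rows of two ternary matrices."""
    eq = A[:, None, :] == B[None, :, :]
    if not include_zero:
        eq &= A[:, None, :] != 0
    return eq.sum(axis=2)


def match_signatures(
    sig_a: SignatureMatrix,
    sig_b: SignatureMatrix,
    n_permutations: int = 100,
    z_threshold: float = 4.0,
    permuted_side: str = "A",
    null_model: str = "pooled",
    permutation_scheme: str = "columns",
    include_zero_matches: bool = True,
    seed: int | None = DEFAULT_SEED,
    rng: np.random.Generator | None = None,
) -> "MatchResults":
    """Match subpopulations of two samples and calibrate by permutation.

    Observed match counts for every ordered pair are compared against a
    null distribution built by randomizing the designated side's signature
    matrix ``n_permutations`` times and recomputing all pairwise counts each
    round.  With ``null_model="pooled"`` (default) all pair-level counts
    from all rounds are pooled into a single null (one shared mean/SD);
    ``null_model="per-pair"`` keeps a separate null per pair.  A pair is
    significant when the null SD is positive and
    ``(observed - null mean) / null SD > z_threshold`` (one-sided:
    significantly GREATER than chance).
    """
    if list(sig_a.gene_ids) != list(sig_b.gene_ids):
        raise AlgorithmError(
            "match_signatures: gene axes differ between "
            f"{sig_a.sample_id or 'A'!r} and {sig_b.sample_id or 'B'!r} "
            "(same IDs in the same order required)"
        )
    if n_permutations < 2:
        raise ConfigurationError("n_permutations must be >= 2")
    if permuted_side not in ("A", "B"):
        raise ConfigurationError("permuted_side must be 'A' or 'B'")
    if null_model not in ("pooled", "per-pair"):
        raise ConfigurationError("null_model must be 'pooled' or 'per-pair'")
    if rng is None:
        rng = np.random.default_rng(seed)

    A, B = sig_a.values, sig_b.values
    observed = _pair_counts(A, B, include_zero_matches)

    target = sig_a if permuted_side == "A" else sig_b
    null_counts = np.empty((n_permutations,) + observed.shape, dtype=np.int64)
    for r in range(n_permutations):
        perm = permute_signature(target, rng, scheme=permutation_scheme)
        if permuted_side == "A":
            null_counts[r] = _pair_counts(perm.values, B, include_zero_matches)
        else:
            null_counts[r] = _pair_counts(A, perm.values, include_zero_matches)

    if null_model == "pooled":
        pm = float(null_counts.mean())
        psd = float(null_counts.std(ddof=1))
        perm_mean = np.full(observed.shape, pm)
        perm_sd = np.full(observed.shape, psd)
    else:
        perm_mean = null_counts.mean(axis=0)
        perm_sd = null_counts.std(axis=0, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - perm_mean) / perm_sd
    defined = perm_sd > 0
    z = np.where(defined, z, np.nan)
    significant = defined & (z > z_threshold)

    rows = []
    for i, a_id in enumerate(sig_a.subpop_ids):
        for j, b_id in enumerate(sig_b.subpop_ids):
            rows.append(
                {
                    "subpop_a": a_id,
                    "subpop_b": b_id,
                    "observed": int(observed[i, j]),
                    "perm_mean": float(perm_mean[i, j]),
                    "perm_sd": float(perm_sd[i, j]),
                    "z": float(z[i, j]) if defined[i, j] else float("nan"),
                    "significant": bool(significant[i, j]),
                }
            )
    pairs = pd.DataFrame(rows)
    meta = {
        "n_permutations": n_permutations,
        "z_threshold": z_threshold,
        "permuted_side": permuted_side,
        "null_model": null_model,
        "permutation_scheme": permutation_scheme,
        "include_zero_matches": include_zero_matches,
        "seed": seed,
        "alpha_a": sig_a.alpha,
        "alpha_b": sig_b.alpha,
        "sample_a": sig_a.sample_id,
        "sample_b": sig_b.sample_id,
        "n_genes": sig_a.n_genes,
    }
    return MatchResults(pairs=pairs, metadata=meta, sig_a=sig_a, sig_b=sig_b)


@dataclass
class MatchResults:
    """Results of :func:`match_signatures` / :meth:`SubpopulationMatching.fit`.

    ``pairs`` holds one row per ordered subpopulation pair with the observed
    match count, the permutation null mean/SD, the z-score (NaN when the
    null SD is zero) and the significance call.
    """

    pairs: pd.DataFrame
    metadata: dict
    sig_a: SignatureMatrix
    sig_b: SignatureMatrix
    _matched_cache: dict = field(default_factory=dict, repr=False)

    def significant_pairs(self) -> list[tuple[int, int]]:
        sel = self.pairs[self.pairs["significant"]]
        return list(zip(sel["subpop_a"].tolist(), sel["subpop_b"].tolist()))

    def mapping(self) -> dict[int, int]:
        """Significant pairs as a dict; raises if any side matches twice."""
        pairs = self.significant_pairs()
        out: dict[int, int] = {}
        for a, b in pairs:
            if a in out or b in out.values():
                raise AlgorithmError("matching is not one-to-one; inspect .pairs instead")
            out[a] = b
        return out

    def matched_genes(self, subpop_a: int, subpop_b: int, *, nonzero_only: bool = False) -> list[str]:
        """Genes where the two signatures agree (optionally on nonzero values).

        The nonzero set is the displayed matched signature; zero-agreements
        still count toward ``observed``.
        """
        key = (subpop_a, subpop_b, nonzero_only)
        if key not in self._matched_cache:
            a = self.sig_a.row(subpop_a)
            b = self.sig_b.row(subpop_b)
            eq = a == b
            if nonzero_only:
                eq = eq & (a != 0)
            genes = [g for g, m in zip(self.sig_a.gene_ids, eq) if m]
            self._matched_cache[key] = genes
        return self._matched_cache[key]

    def summary(self) -> str:
        m = self.metadata
        lines = [
            "Subpopulation matching (ternary gene signatures, permutation null)",
            "=" * 68,
            f"samples: A={m['sample_a'] or '-'}  B={m['sample_b'] or '-'}   genes: {m['n_genes']}",
            f"permutations: {m['n_permutations']} ({m['permutation_scheme']}, side {m['permuted_side']}, "
            f"{m['null_model']} null)   z threshold: {m['z_threshold']}   seed: {m['seed']}",
            "-" * 68,
        ]
        tab = self.pairs.copy()
        tab["z"] = tab["z"].map(lambda v: f"{v:8.3f}" if np.isfinite(v) else "   undef")
        lines.append(
            tab.to_string(
                index=False,
                columns=["subpop_a", "subpop_b", "observed", "perm_mean", "perm_sd", "z", "significant"],
                float_format=lambda v: f"{v:.3f}",
            )
        )
        sig = self.significant_pairs()
        lines.append("-" * 68)
        lines.append(
            "significant pairs: " + (", ".join(f"{a}<->{b}" for a, b in sig) if sig else "none")
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {"metadata": dict(self.metadata), "pairs": []}
        for rec in self.pairs.to_dict(orient="records"):
            rec = dict(rec)
            if rec["significant"]:
                rec["matched_genes_nonzero"] = self.matched_genes(
                    rec["subpop_a"], rec["subpop_b"], nonzero_only=True
                )
            if not np.isfinite(rec["z"]):
                rec["z"] = None  # JSON-safe marker for an undefined z-score
            out["pairs"].append(rec)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


class SubpopulationMatching:
    """Model: match labeled subpopulations between two count samples.

    Wires the full pipeline — library-size x1000 asinh transform, per-sample
    ternary signatures at ``alpha``, permutation-calibrated match test —
    behind a statsmodels-style ``model.fit() -> results`` interface.

    Parameters
    ----------
    counts_a, labels_a
        First (e.g. control) sample and its subpopulation labels.
    counts_b, labels_b
        Second (e.g. treated) sample; must share the gene universe of the
        first sample (same IDs, same order).
    alpha
        Raw Welch-test significance threshold for signature entries.
    """

    def __init__(
        self,
        counts_a: CountMatrix,
        labels_a: ClusterLabels,
        counts_b: CountMatrix,
        labels_b: ClusterLabels,
        alpha: float = 0.001,
        scale_factor: float = 1000.0,
    ) -> None:
        if list(counts_a.gene_ids) != list(counts_b.gene_ids):
            raise AlgorithmError(
                "SubpopulationMatching: the two samples must share an identical gene axis"
            )
        self.counts_a, self.labels_a = counts_a, labels_a
        self.counts_b, self.labels_b = counts_b, labels_b
        self.alpha = alpha
        self.scale_factor = scale_factor

    def signatures(self) -> tuple[SignatureMatrix, SignatureMatrix]:
        sig = []
        for counts, labels in ((self.counts_a, self.labels_a), (self.counts_b, self.labels_b)):
            t = normalize_transform(counts, "asinh1000", self.scale_factor)
            sig.append(compute_signature(t, labels, alpha=self.alpha))
        return sig[0], sig[1]

    def fit(
        self,
        n_permutations: int = 100,
        z_threshold: float = 4.0,
        permuted_side: str = "A",
        null_model: str = "pooled",
        permutation_scheme: str = "columns",
        include_zero_matches: bool = True,
        seed: int | None = DEFAULT_SEED,
    ) -> MatchResults:
        sig_a, sig_b = self.signatures()
        return match_signatures(
            sig_a,
            sig_b,
            n_permutations=n_permutations,
            z_threshold=z_threshold,
            permuted_side=permuted_side,
            null_model=null_model,
            permutation_scheme=permutation_scheme,
            include_zero_matches=include_zero_matches,
            seed=seed,
        )


# ---------------------------------------------------------------------------
# Signature TSV round-trip (genes as rows, subpopulations as columns)


def write_signature(sig: SignatureMatrix, path: str | Path) -> None:
    p = Path(path)
    with open(p, "w") as fh:
        fh.write(f"# sample_id={sig.sample_id}\n")
        fh.write(f"# alpha={sig.alpha!r}\n")
        fh.write("gene\t" + "\t".join(str(s) for s in sig.subpop_ids) + "\n")
        for g, col in zip(sig.gene_ids, sig.values.T):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in col) + "\n")


def read_signature(path: str | Path) -> SignatureMatrix:
    p = Path(path)
    sample_id, alpha = "", 0.001
    genes: list[str] = []
    cols: list[list[int]] = []
    subpop_ids: list[int] | None = None
    with open(p) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("# sample_id="):
                sample_id = line.split("=", 1)[1]
                continue
            if line.startswith("# alpha="):
                alpha = float(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if subpop_ids is None:
                if parts[0] != "gene":
                    raise FormatError(f"{p}: line {i}: expected header starting with 'gene'")
                subpop_ids = [int(s) for s in parts[1:]]
                continue
            if len(parts) != len(subpop_ids) + 1:
                raise FormatError(f"{p}: line {i}: wrong number of columns")
            genes.append(parts[0])
            cols.append([int(v) for v in parts[1:]])
    if subpop_ids is None:
        raise FormatError(f"{p}: empty signature file")
    values = np.asarray(cols, dtype=np.int8).T if cols else np.zeros((len(subpop_ids), 0), np.int8)
    return SignatureMatrix(
        subpop_ids=subpop_ids, gene_ids=genes, values=values, alpha=alpha, sample_id=sample_id
    )
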