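"""Normalizations applied before signature building and differential expression.

Two monotone, sparsity-preserving transforms of library-size-normalized
counts are supported:

``asinh1000``
    v = asinh(1000 * c / L), where c is the UMI count and L the cell's total
    count.  This is the variance-stabilizing transform used upstream of
    signature construction.  The scale factor defaults to 1000.
``lognorm``
    v = ln(1 + s * c / L) with s defaulting to 10000, the log-normalization
    convention of the clustering ecosystem whose detection-fraction /
    log-fold-change thresholds the DE stage uses.

Both map 0 -> 0 and are strictly increasing within a cell, so the nonzero
pattern of the transformed matrix equals that of the counts and per-cell
rank order is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError
from .io import CountMatrix

__all__ = ["TransformedMatrix", "normalize_transform", "DEFAULT_SCALE"]

DEFAULT_SCALE = {"asinh1000": 1000.0, "lognorm": 10000.0}


@dataclass
class TransformedMatrix:
    """Genes x cells real-valued matrix produced by :func:`normalize_transform`."""

    gene_ids: list[str]
    barcodes: list[str]
    values: sp.csr_matrix
    method: str
    scale_factor: float
    sample_id: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def normalize_transform(
    matrix: CountMatrix,
    method: str = "asinh1000",
    scale_factor: float | None = None,
    *,
    literal_sinh: bool = False,
) -> TransformedMatrix:
    """Library-size normalize and transform a count matrix.

    Parameters
    ----------
    matrix
        Validated count matrix (every cell has library size > 0).
    method
        ``"asinh1000"`` or ``"lognorm"`` (see module docstring).
    scale_factor
        Overrides the method default (1000 / 10000).  Must be positive.
    literal_sinh
        For ``asinh1000`` only: apply the (forward) hyperbolic sine instead
        of its inverse.  The forward sinh of normalized values up to the
        scale factor overflows and destroys variance stabilization; the flag
        exists solely for fidelity experiments and is off by default.
    """
    if method not in DEFAULT_SCALE:
        raise ConfigurationError(f"unknown transform method {method!r}")
    s = DEFAULT_SCALE[method] if scale_factor is None else float(scale_factor)
    if not s > 0:
        raise ConfigurationError(f"scale_factor must be > 0, got {s}")
    if literal_sinh and method != "asinh1000":
        raise ConfigurationError("literal_sinh applies only to the asinh1000 method")

    lib = matrix.library_sizes().astype(np.float64)
    coo = sp.coo_matrix(matrix.counts)
    normed = s * coo.data.astype(np.float64) / lib[coo.col]
    if method == "asinh1000":
        if literal_sinh:
            with np.errstate(over="ignore"):  # overflow is the documented hazard
                data = np.sinh(normed)
        else:
            data = np.arcsinh(normed)
    else:
        data = np.log1p(normed)
    values = sp.csr_matrix(
        (data, (coo.row, coo.col)), shape=matrix.counts.shape, dtype=np.float64
    )
    return TransformedMatrix(
        gene_ids=list(matrix.gene_ids),
        barcodes=list(matrix.barcodes),
        values=values,
        method=method,
        scale_factor=s,
        sample_id=matrix.sample_id,
    )
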