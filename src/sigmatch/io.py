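"""Count-matrix data model and readers/writers for the standard formats.

A sample is a genes x cells matrix of UMI counts stored sparse, exchanged on
disk as a CellRanger-style MatrixMarket triplet (``matrix.mtx`` with 1-based
coordinate indices, ``genes.tsv``, ``barcodes.tsv``).  Per-cell subpopulation
labels travel as a 2-column TSV (barcode, subpopulation) and gene sets (e.g.
cell-cycle phases) as a 2-column TSV (gene, category).

Validation is total: any input violating a type invariant raises a
diagnosable :class:`~sigmatch.errors.FormatError` or
:class:`~sigmatch.errors.ValidationError`, never a silent coercion.
Orientation is fixed as rows = genes; transposed inputs are rejected rather
than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .errors import FormatError, ValidationError

__all__ = [
    "CountMatrix",
    "ClusterLabels",
    "GeneSetTable",
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "read_gene_sets",
    "write_gene_sets",
]

#: Minimum cells per subpopulation: the smallest n at which a variance
#: estimate exists in both groups of the unequal-variance t-test under
#: group-vs-rest splits.
MIN_CELLS_PER_SUBPOP = 3


def _check_unique(ids: list[str], what: str, where: str) -> None:
    seen: set[str] = set()
    for i, x in enumerate(ids):
        if x in seen:
            raise ValidationError(f"{where}: duplicate {what} {x!r} at position {i + 1}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Genes x cells non-negative integer UMI counts for one sample.

    Parameters
    ----------
    gene_ids, barcodes
        Ordered, unique identifiers for rows and columns.
    counts
        ``scipy.sparse`` matrix (stored CSR) of shape
        ``(len(gene_ids), len(barcodes))`` with non-negative integer entries.
        Every column (cell) must have a positive library size.
    sample_id
        Free-text sample label carried through downstream results.
    """

    gene_ids: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix
    sample_id: str = ""

    def __post_init__(self) -> None:
        where = f"CountMatrix({self.sample_id or 'unnamed'})"
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        _check_unique(self.gene_ids, "gene ID", where)
        _check_unique(self.barcodes, "barcode", where)
        m = sp.csr_matrix(self.counts)
        if m.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValidationError(
                f"{where}: matrix shape {m.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes "
                "(orientation must be genes x cells)"
            )
        if m.nnz and m.data.min() < 0:
            raise ValidationError(f"{where}: negative count entries")
        if np.issubdtype(m.dtype, np.floating):
            if m.nnz and not np.all(m.data == np.round(m.data)):
                raise ValidationError(f"{where}: non-integral count entries")
            m = m.astype(np.int64)
        m.eliminate_zeros()
        lib = np.asarray(m.sum(axis=0)).ravel()
        zero = np.flatnonzero(lib == 0)
        if zero.size:
            raise ValidationError(
                f"{where}: zero library size for barcode(s) "
                + ", ".join(self.barcodes[i] for i in zero[:5])
            )
        self.counts = m

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def library_sizes(self) -> np.ndarray:
        """Total counts per cell (always > 0 by construction)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class ClusterLabels:
    """Per-cell subpopulation assignment aligned to a :class:`CountMatrix`.

    Subpopulation IDs are contiguous integers starting at 0, in order of
    first appearance along the matrix barcode order.  Every subpopulation
    present must have at least :data:`MIN_CELLS_PER_SUBPOP` cells.
    """

    barcodes: list[str]
    labels: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        where = f"ClusterLabels({self.sample_id or 'unnamed'})"
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (len(self.barcodes),):
            raise ValidationError(f"{where}: one label per barcode required")
        _check_unique(list(self.barcodes), "barcode", where)
        ids, counts = np.unique(self.labels, return_counts=True)
        if ids.size and (ids.min() < 0 or not np.array_equal(ids, np.arange(ids.size))):
            raise ValidationError(f"{where}: subpopulation IDs must be contiguous from 0")
        small = ids[counts < MIN_CELLS_PER_SUBPOP]
        if small.size:
            raise ValidationError(
                f"{where}: subpopulation(s) {small.tolist()} have fewer than "
                f"{MIN_CELLS_PER_SUBPOP} cells"
            )

    @property
    def n_subpops(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def subpop_ids(self) -> list[int]:
        return list(range(self.n_subpops))

    def mask(self, subpop: int) -> np.ndarray:
        return self.labels == subpop

    def as_mapping(self) -> dict[str, int]:
        return dict(zip(self.barcodes, self.labels.tolist()))

    @classmethod
    def from_mapping(
        cls, mapping: dict[str, int], matrix: CountMatrix, sample_id: str | None = None
    ) -> "ClusterLabels":
        """Align a barcode -> subpopulation mapping to ``matrix`` order.

        Raw subpopulation IDs are re-indexed to contiguous integers
        preserving first-appearance order along the matrix barcodes.
        """
        missing = [b for b in matrix.barcodes if b not in mapping]
        if missing:
            raise ValidationError(
                f"labels for sample {matrix.sample_id!r}: missing barcode(s) "
                + ", ".join(missing[:5])
            )
        unknown = [b for b in mapping if b not in set(matrix.barcodes)]
        if unknown:
            raise ValidationError(
                f"labels for sample {matrix.sample_id!r}: unknown barcode(s) "
                + ", ".join(unknown[:5])
            )
        raw = [mapping[b] for b in matrix.barcodes]
        remap: dict[int, int] = {}
        for r in raw:
            if r not in remap:
                remap[r] = len(remap)
        labels = np.array([remap[r] for r in raw], dtype=np.int64)
        return cls(
            barcodes=list(matrix.barcodes),
            labels=labels,
            sample_id=matrix.sample_id if sample_id is None else sample_id,
        )


@dataclass
class GeneSetTable:
    """Named gene sets (category -> ordered unique gene list).

    A gene may belong to several categories (multi-membership is allowed);
    within a category genes are unique.  For cell-cycle scoring the category
    names are the five phases ``G1-S, S, G2, G2-M, M-G1``.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not str(name):
                raise ValidationError("GeneSetTable: empty category name")
            if not genes:
                raise ValidationError(f"GeneSetTable: category {name!r} is empty")
            _check_unique(list(genes), "gene", f"GeneSetTable[{name}]")

    @property
    def categories(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, category: str) -> list[str]:
        return self.sets[category]


# ---------------------------------------------------------------------------
# MatrixMarket triplet I/O


def _triplet_paths(path: str | Path) -> tuple[Path, Path, Path]:
    d = Path(path)
    return d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv"


def _read_id_column(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise FormatError(f"{path}: missing {what} file")
    out: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            token = line.rstrip("\n").split("\t")[0]
            if not token:
                raise FormatError(f"{path}: empty {what} on line {i}")
            out.append(token)
    if not out:
        raise FormatError(f"{path}: no {what} entries")
    return out


def read_counts(path: str | Path, sample_id: str | None = None) -> CountMatrix:
    """Read a MatrixMarket triplet directory into a :class:`CountMatrix`.

    ``path`` is a directory containing ``matrix.mtx`` (coordinate format,
    1-based indices, genes as rows), ``genes.tsv`` and ``barcodes.tsv``.
    """
    mtx, genes_p, barcodes_p = _triplet_paths(path)
    genes = _read_id_column(genes_p, "gene ID")
    barcodes = _read_id_column(barcodes_p, "barcode")
    if not mtx.exists():
        raise FormatError(f"{mtx}: missing matrix file")
    try:
        m = spio.mmread(mtx)
    except Exception as exc:  # malformed header, bad indices, nnz mismatch
        raise FormatError(f"{mtx}: {exc}") from exc
    if m.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{mtx}: declared shape {m.shape} does not match "
            f"{len(genes)} genes / {len(barcodes)} barcodes"
        )
    try:
        return CountMatrix(
            gene_ids=genes,
            barcodes=barcodes,
            counts=sp.csr_matrix(m),
            sample_id=Path(path).name if sample_id is None else sample_id,
        )
    except ValidationError as exc:
        raise FormatError(f"{mtx}: {exc}") from exc


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write ``matrix`` as a MatrixMarket triplet; round-trips bit-exactly."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    mtx, genes_p, barcodes_p = _triplet_paths(d)
    spio.mmwrite(str(mtx), sp.coo_matrix(matrix.counts), field="integer")
    # mmwrite may append .mtx; normalise to the exact triplet name
    written = Path(str(mtx))
    if not written.exists() and Path(str(mtx) + ".mtx").exists():
        Path(str(mtx) + ".mtx").rename(written)
    genes_p.write_text("".join(g + "\n" for g in matrix.gene_ids))
    barcodes_p.write_text("".join(b + "\n" for b in matrix.barcodes))


# ---------------------------------------------------------------------------
# Label and gene-set TSVs


def read_labels(path: str | Path, matrix: CountMatrix) -> ClusterLabels:
    """Read a (barcode, subpopulation) TSV validated against ``matrix``."""
    p = Path(path)
    mapping: dict[str, int] = {}
    with open(p) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{p}: line {i}: expected 2 tab-separated columns")
            bc, lab = parts
            if bc in mapping:
                raise FormatError(f"{p}: line {i}: duplicate barcode {bc!r}")
            try:
                mapping[bc] = int(lab)
            except ValueError as exc:
                raise FormatError(f"{p}: line {i}: non-integer subpopulation {lab!r}") from exc
    if not mapping:
        raise FormatError(f"{p}: empty label file")
    return ClusterLabels.from_mapping(mapping, matrix)


def write_labels(labels: ClusterLabels, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{b}\t{s}\n" for b, s in zip(labels.barcodes, labels.labels.tolist()))
    )


def read_gene_sets(path: str | Path) -> GeneSetTable:
    """Read a (gene, category) TSV; duplicate rows collapse to one membership."""
    p = Path(path)
    sets: dict[str, list[str]] = {}
    with open(p) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{p}: line {i}: expected 2 tab-separated columns")
            gene, cat = parts
            if not cat:
                raise FormatError(f"{p}: line {i}: empty category name")
            if not gene:
                raise FormatError(f"{p}: line {i}: empty gene name")
            members = sets.setdefault(cat, [])
            if gene not in members:
                members.append(gene)
    if not sets:
        raise FormatError(f"{p}: empty gene-set file")
    return GeneSetTable(sets=sets)


def write_gene_sets(table: GeneSetTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cat, genes in table.sets.items():
            for g in genes:
                fh.write(f"{g}\t{cat}\n")


def labels_frame(labels: ClusterLabels) -> pd.DataFrame:
    """Labels as a two-column DataFrame (barcode, subpopulation)."""
    return pd.DataFrame({"barcode": labels.barcodes, "subpopulation": labels.labels})
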