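import numpy as np
import pytest
import scipy.sparse as sp

from sigmatch import ClusterLabels, CountMatrix, TransformedMatrix


def make_counts(array, sample_id="s", gene_prefix="g", bc_prefix="c") -> CountMatrix:
    """CountMatrix from a dense genes x cells array with generated IDs."""
    arr = np.asarray(array)
    return CountMatrix(
        gene_ids=[f"{gene_prefix}{i}" for i in range(arr.shape[0])],
        barcodes=[f"{bc_prefix}{j}" for j in range(arr.shape[1])],
        counts=sp.csr_matrix(arr),
        sample_id=sample_id,
    )


def make_transformed(array, method="asinh1000", sample_id="s") -> TransformedMatrix:
    """TransformedMatrix directly from dense values (for constructed fixtures)."""
    arr = np.asarray(array, dtype=float)
    return TransformedMatrix(
        gene_ids=[f"g{i}" for i in range(arr.shape[0])],
        barcodes=[f"c{j}" for j in range(arr.shape[1])],
        values=sp.csr_matrix(arr),
        method=method,
        scale_factor=1000.0 if method == "asinh1000" else 10000.0,
        sample_id=sample_id,
    )


def make_labels(assignments, sample_id="s") -> ClusterLabels:
    arr = np.asarray(assignments, dtype=np.int64)
    return ClusterLabels(
        barcodes=[f"c{j}" for j in range(arr.size)], labels=arr, sample_id=sample_id
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
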