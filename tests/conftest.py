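import numpy as np
import pandas as pd
import pytest

from polyhyb import ExpressionSet


@pytest.fixture
def tiny_marker_matrix():
    """Eight fragments covering every origin class and alteration type."""
    rows = {
        # fragment_id: (maternal, paternal, hybrid, allopolyploid_1)
        "f_common_kept": (1, 1, 1, 1),
        "f_mat_kept": (1, 0, 1, 1),
        "f_pat_kept": (0, 1, 1, 1),
        "f_h_only": (1, 0, 0, 0),
        "f_p_only": (1, 1, 1, 0),
        "f_h_p": (0, 1, 0, 1),
        "f_novel_kept": (0, 0, 1, 1),
        "f_novel_lost": (0, 0, 1, 0),
    }
    return pd.DataFrame(
        rows.values(),
        index=pd.Index(rows.keys(), name="fragment_id"),
        columns=["maternal", "paternal", "hybrid", "allopolyploid_1"],
    )


@pytest.fixture
def tiny_msap_table():
    """Four sites, one per hybrid state, with assorted allopolyploid states."""
    return pd.DataFrame(
        {
            "hybrid_H": [1, 0, 1, 0],
            "hybrid_M": [1, 1, 0, 0],
            "allopolyploid_1_H": [0, 1, 1, 1],
            "allopolyploid_1_M": [1, 1, 0, 1],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="site_id"),
    )


@pytest.fixture
def small_expression_set():
    """Five genes with hand-chosen counts giving round FPKM values."""
    genes = pd.Index([f"g{i}" for i in range(1, 6)], name="gene_id")
    counts = pd.DataFrame(
        {
            "maternal": [10, 0, 200, 40, 5],
            "paternal": [10, 50, 100, 10, 5],
            "hybrid": [40, 25, 0, 20, 5],
        },
        index=genes,
    )
    lengths = pd.Series([1000, 500, 2000, 1000, 800], index=genes, name="length_bp")
    libsizes = pd.Series(
        {"maternal": 1_000_000, "paternal": 1_000_000, "hybrid": 1_000_000},
        name="library_size",
    )
    return ExpressionSet(counts=counts, lengths=lengths, library_sizes=libsizes)


def build_marker_matrix_from_counts(
    n_common, n_maternal, n_paternal, n_novel, allo_same_as_hybrid=True
):
    """Deterministically construct a matrix with given hybrid-present class counts."""
    blocks = []
    for n, (m, p) in zip(
        (n_common, n_maternal, n_paternal, n_novel),
        ((1, 1), (1, 0), (0, 1), (0, 0)),
    ):
        blocks.append(np.tile([m, p, 1, 1 if allo_same_as_hybrid else 0], (n, 1)))
    data = np.vstack(blocks)
    index = pd.Index([f"frag_{i}" for i in range(len(data))], name="fragment_id")
    return pd.DataFrame(
        data, index=index, columns=["maternal", "paternal", "hybrid", "allopolyploid_1"]
    )
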