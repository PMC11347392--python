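import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sttme.io import SpotMatrix
from sttme.synth import make_section


def make_spot_matrix(counts, barcodes=None, gene_ids=None, in_tissue=1):
    """Hand-rolled SpotMatrix for small fixtures."""
    counts = np.asarray(counts)
    n_spots, n_genes = counts.shape
    barcodes = barcodes or [f"BC{i:03d}" for i in range(n_spots)]
    gene_ids = gene_ids or [f"G{j:03d}" for j in range(n_genes)]
    rows = np.arange(n_spots)
    pos = pd.DataFrame({
        "in_tissue": in_tissue,
        "array_row": rows,
        "array_col": rows % 2 + 2 * (rows // 2) * 0,  # parity-matching cols
        "pxl_row_in_fullres": rows * 100,
        "pxl_col_in_fullres": rows * 100,
    }, index=pd.Index(barcodes, name="barcode"))
    pos["array_col"] = rows % 2  # row i at (i, i % 2): parity matches
    return SpotMatrix(counts=sp.csr_matrix(counts),
                      barcodes=np.array(barcodes, object),
                      gene_ids=np.array(gene_ids, object), positions=pos)


@pytest.fixture(scope="session")
def small_section():
    """One default synthetic section shared by read-only tests."""
    return make_section(seed=7)


@pytest.fixture(scope="session")
def tiny_section():
    """A fast, small section for pipeline-style tests."""
    return make_section(n_spots=200, n_genes=600, n_chroms=3, cnv_genes=120,
                        seed=11)
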