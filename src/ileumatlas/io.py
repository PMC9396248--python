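"""Reading and writing 10x-style Matrix Market triplet directories.

A count matrix directory holds ``matrix.mtx`` (genes x cells, integer
triplets, CellRanger orientation), ``features.tsv`` (gene_id, gene_symbol,
mito flag plus any extra per-gene columns) and ``barcodes.tsv`` (barcode
plus any per-cell metadata columns such as sample/animal/tissue).  In
memory the matrix is an :class:`anndata.AnnData` with cells as rows.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["write_mtx", "read_mtx"]


def write_mtx(adata: ad.AnnData, dir_path: str | os.PathLike) -> None:
    """Write ``adata`` as matrix.mtx + features.tsv + barcodes.tsv.

    Counts are written genes-as-rows (10x convention).  ``adata.var`` and
    ``adata.obs`` columns are preserved verbatim in the two TSV sidecars so
    the round trip through :func:`read_mtx` is lossless.
    """
    dir_path = os.fspath(dir_path)
    os.makedirs(dir_path, exist_ok=True)
    x = sp.coo_matrix(adata.X.T if sp.issparse(adata.X) else np.asarray(adata.X).T)
    scipy.io.mmwrite(os.path.join(dir_path, "matrix.mtx"), x, field="integer")
    var = adata.var.copy()
    var.insert(0, "gene_id", adata.var_names)
    var.to_csv(os.path.join(dir_path, "features.tsv"), sep="\t", index=False)
    obs = adata.obs.copy()
    obs.insert(0, "barcode", adata.obs_names)
    obs.to_csv(os.path.join(dir_path, "barcodes.tsv"), sep="\t", index=False)


def read_mtx(dir_path: str | os.PathLike) -> ad.AnnData:
    """Read a directory written by :func:`write_mtx` back into AnnData."""
    dir_path = os.fspath(dir_path)
    x = scipy.io.mmread(os.path.join(dir_path, "matrix.mtx"))
    counts = sp.csr_matrix(x.T)
    var = pd.read_csv(os.path.join(dir_path, "features.tsv"), sep="\t")
    obs = pd.read_csv(os.path.join(dir_path, "barcodes.tsv"), sep="\t")
    var = var.set_index("gene_id")
    var.index = var.index.astype(str)
    var.index.name = None
    obs = obs.set_index("barcode")
    obs.index = obs.index.astype(str)
    obs.index.name = None
    # 0-cell or 0-gene matrices: mmread still records the dimensions
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    return adata
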