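"""Matrix Market triplet I/O (10x-style directory layout).

A dataset directory holds::

    matrix.mtx    sparse counts, genes as rows, cells as columns
    genes.tsv     one gene id per row (header: gene_id)
    barcodes.tsv  cell barcode + annotations (header: barcode, sample,
                  mito_frac [, planted_state])

Values and annotations round-trip losslessly through
:func:`write_matrix` / :func:`read_matrix`.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from anndata import AnnData

from .errors import FormatError
from .simulate import NORM_STATE_KEY


def write_matrix(adata: AnnData, path: str | os.PathLike) -> None:
    """Write an annotated cell x gene matrix as an MTX triplet directory."""
    path = str(path)
    os.makedirs(path, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    mmwrite(os.path.join(path, "matrix.mtx"), X.T.tocoo())  # genes x cells

    genes = pd.DataFrame({"gene_id": adata.var_names})
    genes.to_csv(os.path.join(path, "genes.tsv"), sep="\t", index=False)

    cols = {"barcode": adata.obs_names}
    for c in ("sample", "mito_frac", "planted_state"):
        if c in adata.obs:
            cols[c] = adata.obs[c].to_numpy()
    pd.DataFrame(cols).to_csv(os.path.join(path, "barcodes.tsv"), sep="\t", index=False)


def _validate_mtx(mtx_path: str) -> None:
    """Single-pass structural check producing line-numbered errors."""
    with open(mtx_path) as fh:
        header = fh.readline()
        if not header.startswith("%%MatrixMarket"):
            raise FormatError(f"{mtx_path}:1: missing MatrixMarket banner")
        lineno = 1
        dims = None
        for line in fh:
            lineno += 1
            if line.startswith("%"):
                continue
            parts = line.split()
            if dims is None:
                if len(parts) != 3:
                    raise FormatError(
                        f"{mtx_path}:{lineno}: size line must have 3 fields"
                    )
                dims = tuple(int(p) for p in parts)
                continue
            if len(parts) != 3:
                raise FormatError(
                    f"{mtx_path}:{lineno}: entry must have 3 fields, got {len(parts)}"
                )
            try:
                r, c = int(parts[0]), int(parts[1])
                float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{mtx_path}:{lineno}: unparsable entry") from exc
            if not (1 <= r <= dims[0]) or not (1 <= c <= dims[1]):
                raise FormatError(
                    f"{mtx_path}:{lineno}: index ({r}, {c}) outside declared "
                    f"dimensions {dims[0]} x {dims[1]}"
                )
        if dims is None:
            raise FormatError(f"{mtx_path}: no size line found")


def read_matrix(path: str | os.PathLike) -> AnnData:
    """Read a triplet directory back into an AnnData (raw-counts state)."""
    path = str(path)
    mtx_path = os.path.join(path, "matrix.mtx")
    for required in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        if not os.path.exists(os.path.join(path, required)):
            raise FormatError(f"missing {required} in {path}")
    _validate_mtx(mtx_path)
    try:
        M = mmread(mtx_path)
    except Exception as exc:  # pragma: no cover - _validate_mtx catches most
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc

    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t")
    barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t")
    if "gene_id" not in genes.columns:
        raise FormatError("genes.tsv must have a gene_id column")
    if "barcode" not in barcodes.columns:
        raise FormatError("barcodes.tsv must have a barcode column")

    X = sp.csr_matrix(M.T)  # cells x genes
    if X.shape[0] != len(barcodes) or X.shape[1] != len(genes):
        raise FormatError(
            f"matrix is {X.shape[0]} cells x {X.shape[1]} genes but sidecars "
            f"list {len(barcodes)} barcodes and {len(genes)} genes"
        )
    obs = barcodes.set_index("barcode")
    obs.index.name = "cell"
    if "sample" in obs:
        obs["sample"] = obs["sample"].astype("category")
    var = pd.DataFrame(index=pd.Index(genes["gene_id"], name="gene_id"))
    adata = AnnData(X=X.astype(np.float64), obs=obs, var=var)
    adata.uns[NORM_STATE_KEY] = "raw"
    return adata


def write_ground_truth(truth, path: str | os.PathLike) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def write_deg_truth(truth, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"gene": truth.deg_genes, "planted_log2fc": truth.log2fc.to_numpy()}
    ).to_csv(path, sep="\t", index=False)
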