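"""Cell-retention filters and normalization.

Retention keeps cells with a minimum total count of 10,000, at least 1,500
detected genes, and a mitochondrial read fraction below 25% (defaults of
:class:`QCParams`; synthetic data uses thresholds scaled to its simulated
depth).  Normalization is counts-per-million — each retained cell is scaled
to a library size of 10^6 ("transcript-per-million" on UMI-style counts has
no gene-length term).  Downstream model input is log1p of the per-million
values, min–max scaled per gene to [0, 1] with the scaler fitted on the
training cells, persisted, and applied with clipping at inference so no
information leaks from evaluation data.

The normalization state of a matrix is tracked in
``adata.uns["norm_state"]`` and advances one way:
``raw -> per_million -> scaled``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .errors import (
    DegenerateCellError,
    MissingGeneError,
    ParameterError,
    StateError,
)
from .simulate import NORM_STATE_KEY


@dataclass
class QCParams:
    min_total_counts: int = 10_000
    min_genes: int = 1_500
    max_mito_fraction: float = 0.25

    def validate(self) -> None:
        if self.min_total_counts < 0 or self.min_genes < 0:
            raise ParameterError("QC thresholds must be >= 0")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ParameterError("max_mito_fraction must lie in [0, 1]")


def _norm_state(adata: AnnData) -> str:
    return adata.uns.get(NORM_STATE_KEY, "raw")


def _require_state(adata: AnnData, state: str, op: str) -> None:
    got = _norm_state(adata)
    if got != state:
        raise StateError(f"{op} requires a matrix in '{state}' state, got '{got}'")


def annotate_qc(adata: AnnData, mito_prefix: str = "MT-") -> AnnData:
    """Attach per-cell total_counts, n_genes and mito_frac annotations.

    ``mito_frac`` is taken from an existing obs column when present;
    otherwise it is computed from genes whose identifier starts with
    ``mito_prefix``.
    """
    X = adata.X
    if sp.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
        detected = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        totals = X.sum(axis=1)
        detected = (X > 0).sum(axis=1)
    adata.obs["total_counts"] = totals
    adata.obs["n_genes"] = detected.astype(int)
    if "mito_frac" not in adata.obs:
        is_mito = adata.var_names.str.startswith(mito_prefix)
        if is_mito.any():
            mito_counts = np.asarray(X[:, is_mito].sum(axis=1)).ravel()
            with np.errstate(invalid="ignore", divide="ignore"):
                adata.obs["mito_frac"] = np.where(totals > 0, mito_counts / totals, 0.0)
        else:
            adata.obs["mito_frac"] = 0.0
    return adata


def filter_cells(adata: AnnData, params: QCParams | None = None) -> AnnData:
    """Keep cells passing all three retention rules; order preserved.

    A cell is retained iff total counts >= min_total_counts AND detected
    genes >= min_genes AND mito fraction < max_mito_fraction.  Counts of
    removals per rule are stored in ``result.uns["qc_log"]``.
    """
    params = params or QCParams()
    params.validate()
    _require_state(adata, "raw", "filter_cells")
    annotate_qc(adata)
    totals = adata.obs["total_counts"].to_numpy()
    genes = adata.obs["n_genes"].to_numpy()
    mito = adata.obs["mito_frac"].to_numpy()

    ok_total = totals >= params.min_total_counts
    ok_genes = genes >= params.min_genes
    ok_mito = mito < params.max_mito_fraction
    keep = ok_total & ok_genes & ok_mito

    out = adata[keep].copy()
    out.uns[NORM_STATE_KEY] = "raw"
    out.uns["qc_log"] = {
        "n_input": int(adata.n_obs),
        "n_retained": int(keep.sum()),
        "removed_low_total": int((~ok_total).sum()),
        "removed_few_genes": int((~ok_genes).sum()),
        "removed_high_mito": int((~ok_mito).sum()),
        "removed_any": int((~keep).sum()),
    }
    return out


def qc_report(adata: AnnData) -> pd.DataFrame:
    """The qc_log of a filtered matrix as a one-row table."""
    log = adata.uns.get("qc_log")
    if log is None:
        raise StateError("matrix has no qc_log; run filter_cells first")
    return pd.DataFrame([log])


def per_million_normalize(adata: AnnData) -> AnnData:
    """Scale each cell to a total of 10^6 (counts-per-million)."""
    _require_state(adata, "raw", "per_million_normalize")
    X = adata.X
    totals = (
        np.asarray(X.sum(axis=1)).ravel() if sp.issparse(X) else X.sum(axis=1)
    )
    if np.any(totals <= 0):
        bad = list(np.asarray(adata.obs_names)[totals <= 0][:5])
        raise DegenerateCellError(
            f"{int((totals <= 0).sum())} cell(s) with zero total counts "
            f"(e.g. {bad}); filter before normalizing"
        )
    out = adata.copy()
    factors = 1e6 / totals
    if sp.issparse(out.X):
        out.X = sp.diags(factors) @ out.X.tocsr()
    else:
        out.X = out.X * factors[:, None]
    out.uns[NORM_STATE_KEY] = "per_million"
    return out


@dataclass
class GeneScaler:
    """Per-gene min–max scaler fitted on log1p per-million values."""

    genes: list[str]
    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, L: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        out = (L - self.mins[None, :]) / safe[None, :]
        out[:, span <= 0] = 0.0  # constant gene -> 0 by convention
        return np.clip(out, 0.0, 1.0)

    def inverse_transform(self, S: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        return S * span[None, :] + self.mins[None, :]

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "mins": [float(v) for v in self.mins],
            "maxs": [float(v) for v in self.maxs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneScaler":
        return cls(
            genes=list(d["genes"]),
            mins=np.asarray(d["mins"], dtype=np.float64),
            maxs=np.asarray(d["maxs"], dtype=np.float64),
        )


def log_and_scale(
    adata: AnnData,
    gene_order: Sequence[str],
    scaler: GeneScaler | None = None,
) -> tuple[AnnData, GeneScaler]:
    """Restrict to ``gene_order``, log1p, and min–max scale per gene.

    Fits the scaler when none is given (training time); otherwise applies
    the persisted scaler with clipping to [0, 1] (inference time).  Returns
    the dense scaled matrix as a new AnnData in 'scaled' state, plus the
    scaler in use.
    """
    _require_state(adata, "per_million", "log_and_scale")
    gene_order = list(gene_order)
    missing = [g for g in gene_order if g not in adata.var_names]
    if missing:
        raise MissingGeneError(f"genes not in matrix: {missing[:10]}")
    if scaler is not None and list(scaler.genes) != gene_order:
        raise MissingGeneError("scaler gene order does not match requested gene_order")

    sub = adata[:, gene_order]
    X = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X)
    L = np.log1p(X)
    if scaler is None:
        scaler = GeneScaler(
            genes=gene_order,
            mins=L.min(axis=0) if L.shape[0] else np.zeros(len(gene_order)),
            maxs=L.max(axis=0) if L.shape[0] else np.zeros(len(gene_order)),
        )
    S = scaler.transform(L)

    out = AnnData(
        X=S,
        obs=adata.obs.copy(),
        var=pd.DataFrame(index=pd.Index(gene_order, name="gene_id")),
    )
    out.uns.update({k: v for k, v in adata.uns.items()})
    out.uns[NORM_STATE_KEY] = "scaled"
    return out, scaler


#: optional imputation hook applied between QC and normalization; the
#: default is the identity (the synthetic data needs no imputation and
#: external imputation tools are outside this package's scope).
Imputer = Callable[[AnnData], AnnData]


def identity_imputer(adata: AnnData) -> AnnData:
    return adata


def qc_params_to_dict(params: QCParams) -> dict:
    return asdict(params)
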