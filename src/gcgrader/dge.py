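"""Differential gene expression between two cell groups.

Per gene, a Welch unequal-variance t-test is applied to log1p per-million
values, p-values are Benjamini–Hochberg adjusted across all tested genes,
and a gene is called significant when q <= max_fdr and |log2FC| >=
min_abs_log2fc (defaults 0.01 and 1.5).  The fold change is computed on the
linear per-million scale, group A over group B, with a small epsilon guard:

    log2FC = log2((mean_A + eps) / (mean_B + eps)),   eps = 1e-9

Group A is by convention the fertility-associated (polytocous or FS) group,
so positive log2FC means enriched with fertility support.

An optional variance-overestimation variant (both variance terms divided by
group A's size, the conservative convention of common single-cell
toolkits) is available via ``method="overestimated_variance"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, InsufficientDataError, SchemaError, StateError
from .simulate import NORM_STATE_KEY

_VAR_FLOOR = 1e-12
_FC_EPS = 1e-9


@dataclass
class DEGThresholds:
    max_fdr: float = 0.01
    min_abs_log2fc: float = 1.5

    def validate(self) -> None:
        if not 0 < self.max_fdr <= 1:
            raise DomainError("max_fdr must lie in (0, 1]")
        if self.min_abs_log2fc < 0:
            raise DomainError("min_abs_log2fc must be >= 0")


def welch_t(
    values_a, values_b, method: str = "welch"
) -> tuple[float, float, float]:
    """Welch's t statistic, Welch–Satterthwaite df, and two-sided p.

    t = (m_a - m_b) / sqrt(s2_a/n_a + s2_b/n_b); variances are floored at
    1e-12 so zero-variance groups with equal means give t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    na, nb = a.size, b.size
    va = max(a.var(ddof=1), _VAR_FLOOR)
    vb = max(b.var(ddof=1), _VAR_FLOOR)
    if method == "welch":
        term_a, term_b = va / na, vb / nb
    elif method == "overestimated_variance":
        term_a = va / na
        term_b = vb / na  # both terms over group A's size: inflates the SE
    else:
        raise DomainError(f"unknown t-test method: {method!r}")
    se2 = term_a + term_b
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (term_a**2 / (na - 1) + term_b**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def _welch_t_vec(
    A: np.ndarray, B: np.ndarray, method: str = "welch"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch test over columns (genes) of two cell x gene arrays."""
    na, nb = A.shape[0], B.shape[0]
    if na < 2 or nb < 2:
        raise InsufficientDataError("each group needs at least 2 cells")
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va = np.maximum(A.var(axis=0, ddof=1), _VAR_FLOOR)
    vb = np.maximum(B.var(axis=0, ddof=1), _VAR_FLOOR)
    if method == "welch":
        ta, tb = va / na, vb / nb
    elif method == "overestimated_variance":
        ta, tb = va / na, vb / na
    else:
        raise DomainError(f"unknown t-test method: {method!r}")
    se2 = ta + tb
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (ta**2 / (na - 1) + tb**2 / (nb - 1))
    p = np.minimum(2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return t, df, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_genes(
    adata_a: AnnData,
    adata_b: AnnData,
    thresholds: DEGThresholds | None = None,
    method: str = "welch",
    direction: str = "both",
) -> pd.DataFrame:
    """Per-gene DGE table between group A (fertility-associated) and B.

    Both matrices must be in per-million state over the same gene set.
    Genes expressed in zero cells of both groups are excluded from testing
    and from the BH family; the ``tested`` column marks the family that also
    serves as the universe of downstream overlap tests.  Rows are sorted by
    q ascending, then |log2FC| descending, then gene id.
    """
    thresholds = thresholds or DEGThresholds()
    thresholds.validate()
    for m, name in ((adata_a, "A"), (adata_b, "B")):
        if m.uns.get(NORM_STATE_KEY) != "per_million":
            raise StateError(f"group {name} must be in per_million state")
    if list(adata_a.var_names) != list(adata_b.var_names):
        raise SchemaError("gene sets of the two groups differ")
    if direction not in ("both", "up"):
        raise DomainError("direction must be 'both' or 'up'")

    A = adata_a.X.toarray() if sp.issparse(adata_a.X) else np.asarray(adata_a.X)
    B = adata_b.X.toarray() if sp.issparse(adata_b.X) else np.asarray(adata_b.X)

    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    tested = (mean_a > 0) | (mean_b > 0)

    log2fc = np.log2((mean_a + _FC_EPS) / (mean_b + _FC_EPS))
    t = np.full(A.shape[1], np.nan)
    df = np.full(A.shape[1], np.nan)
    p = np.full(A.shape[1], np.nan)
    q = np.full(A.shape[1], np.nan)
    if tested.any():
        tt, tdf, tp = _welch_t_vec(
            np.log1p(A[:, tested]), np.log1p(B[:, tested]), method=method
        )
        t[tested], df[tested], p[tested] = tt, tdf, tp
        q[tested] = bh_adjust(tp)

    if direction == "both":
        fc_ok = np.abs(log2fc) >= thresholds.min_abs_log2fc
    else:
        fc_ok = log2fc >= thresholds.min_abs_log2fc
    significant = tested & (q <= thresholds.max_fdr) & fc_ok

    table = pd.DataFrame(
        {
            "gene": adata_a.var_names,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "pval": p,
            "qval": q,
            "tested": tested,
            "significant": significant,
        }
    )
    table = table.sort_values(
        by=["qval", "log2fc", "gene"],
        key=lambda col: -col.abs() if col.name == "log2fc" else col,
        na_position="last",
    ).reset_index(drop=True)
    return table


def significant_genes(table: pd.DataFrame) -> list[str]:
    return table.loc[table["significant"], "gene"].tolist()


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
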