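"""Confidence-thresholded FS quantification and DEG-set overlap validation.

Each cell receives two class probabilities from the classifier; it is
assigned the arg-max class only when the maximum probability reaches the
confidence threshold (default 0.95), otherwise it is left ambiguous and
excluded from class-specific interpretation.  The headline FS percentage
uses confident cells as the denominator (ambiguous cells say nothing about
class composition); the percentage over all cells is also reported.

Generalizability is validated by intersecting the within-sample DEG sets
with the model-training DEG set: the three-set Venn regions are counted
exactly, and each pairwise overlap gets an upper-tail hypergeometric
p-value against the universe of genes tested in both analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.stats import hypergeom

from .dge import DEGThresholds, rank_genes
from .errors import DomainError, QuantificationError
from .simulate import NORM_STATE_KEY

AMBIGUOUS = "ambiguous"


@dataclass
class ClassificationResult:
    """Per-cell confident labels and the per-sample FS summary."""

    probabilities: pd.DataFrame  # index: cell; columns p_nfs, p_fs
    labels: pd.Series  # FS / NFS / ambiguous per cell
    threshold: float
    sample: pd.Series | None = None
    summary: pd.DataFrame = field(default=None)

    @property
    def n_fs(self) -> int:
        return int((self.labels == "FS").sum())

    @property
    def n_nfs(self) -> int:
        return int((self.labels == "NFS").sum())

    @property
    def n_ambiguous(self) -> int:
        return int((self.labels == AMBIGUOUS).sum())

    @property
    def fs_percentage(self) -> float:
        """FS share of confident cells, in percent."""
        confident = self.n_fs + self.n_nfs
        if confident == 0:
            raise QuantificationError("no confident cells; cannot compute FS percentage")
        return 100.0 * self.n_fs / confident

    @property
    def fs_percentage_of_all(self) -> float:
        return 100.0 * self.n_fs / len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out["label"] = self.labels
        if self.sample is not None:
            out["sample"] = self.sample
        return out


def classify_with_threshold(
    probabilities: np.ndarray,
    threshold: float = 0.95,
    cell_ids=None,
    sample=None,
    classes: tuple[str, str] = ("NFS", "FS"),
) -> ClassificationResult:
    """Arg-max labels gated by the confidence threshold.

    ``probabilities`` must be normalized per cell (rows sum to 1); cells
    whose maximum probability falls below ``threshold`` become ambiguous.
    """
    P = np.asarray(probabilities, dtype=np.float64)
    if P.ndim != 2 or P.shape[1] != 2:
        raise DomainError("probabilities must be an (N, 2) array")
    if not 0.5 < threshold <= 1.0:
        raise DomainError("threshold must lie in (0.5, 1]")
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6) or np.any(P < -1e-12):
        raise DomainError("probabilities must be nonnegative and sum to 1 per cell")

    idx = pd.Index(cell_ids if cell_ids is not None else range(P.shape[0]), name="cell")
    probs = pd.DataFrame(P, columns=["p_nfs", "p_fs"], index=idx)
    winner = np.asarray(classes)[P.argmax(axis=1)]
    confident = P.max(axis=1) >= threshold
    labels = pd.Series(
        np.where(confident, winner, AMBIGUOUS), index=idx, name="label"
    )
    sample_series = (
        pd.Series(np.asarray(sample), index=idx, name="sample")
        if sample is not None
        else None
    )

    result = ClassificationResult(
        probabilities=probs, labels=labels, threshold=threshold, sample=sample_series
    )
    rows = []
    groups = (
        [(s, labels[sample_series == s]) for s in pd.unique(sample_series)]
        if sample_series is not None
        else [("all", labels)]
    )
    for name, lab in groups:
        n_fs = int((lab == "FS").sum())
        n_nfs = int((lab == "NFS").sum())
        n_amb = int((lab == AMBIGUOUS).sum())
        conf = n_fs + n_nfs
        rows.append(
            {
                "sample": name,
                "n_cells": len(lab),
                "n_fs": n_fs,
                "n_nfs": n_nfs,
                "n_ambiguous": n_amb,
                "fs_pct_confident": 100.0 * n_fs / conf if conf else np.nan,
                "fs_pct_all": 100.0 * n_fs / len(lab) if len(lab) else np.nan,
            }
        )
    result.summary = pd.DataFrame(rows)
    return result


def within_sample_dge(
    adata: AnnData,
    result: ClassificationResult,
    thresholds: DEGThresholds | None = None,
) -> pd.DataFrame:
    """DGE between predicted-FS and predicted-NFS confident cells.

    ``adata`` must be the per-million matrix of the same cells the
    classification refers to; ambiguous cells are excluded.  Delegates to
    :func:`gcgrader.dge.rank_genes` with FS as group A.
    """
    labels = result.labels
    missing = labels.index.difference(adata.obs_names)
    if len(missing):
        raise QuantificationError(
            f"classification refers to {len(missing)} cells absent from the matrix"
        )
    fs_cells = labels.index[labels == "FS"]
    nfs_cells = labels.index[labels == "NFS"]
    if len(fs_cells) == 0 or len(nfs_cells) == 0:
        raise QuantificationError(
            f"need confident cells in both classes, got {len(fs_cells)} FS "
            f"and {len(nfs_cells)} NFS"
        )
    a = adata[fs_cells].copy()
    b = adata[nfs_cells].copy()
    a.uns[NORM_STATE_KEY] = adata.uns.get(NORM_STATE_KEY)
    b.uns[NORM_STATE_KEY] = adata.uns.get(NORM_STATE_KEY)
    return rank_genes(a, b, thresholds)


def venn_regions(set_a, set_b, set_c) -> dict[str, int]:
    """Exact counts of the 7 disjoint regions of three sets."""
    A, B, C = set(set_a), set(set_b), set(set_c)
    return {
        "a_only": len(A - B - C),
        "b_only": len(B - A - C),
        "c_only": len(C - A - B),
        "ab_only": len((A & B) - C),
        "ac_only": len((A & C) - B),
        "bc_only": len((B & C) - A),
        "abc": len(A & B & C),
    }


def hypergeom_overlap_test(
    overlap: int, size_a: int, size_b: int, universe: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, size_a, size_b)."""
    overlap, size_a, size_b, universe = (
        int(overlap),
        int(size_a),
        int(size_b),
        int(universe),
    )
    if not (0 <= size_a <= universe and 0 <= size_b <= universe):
        raise DomainError("set sizes must lie within the universe")
    if not 0 <= overlap <= min(size_a, size_b):
        raise DomainError("overlap must lie in [0, min(size_a, size_b)]")
    return float(hypergeom.sf(overlap - 1, universe, size_a, size_b))


@dataclass
class OverlapResult:
    """Venn regions of the three DEG sets plus pairwise overlap tests."""

    regions: dict[str, int]
    set_sizes: dict[str, int]
    universe: int
    pairwise: pd.DataFrame  # columns: pair, overlap, size_1, size_2, pvalue

    def to_frame(self) -> pd.DataFrame:
        rows = [{"region": k, "count": v} for k, v in self.regions.items()]
        return pd.DataFrame(rows)


def overlap_report(
    training_degs,
    poly_degs,
    mono_degs,
    universe: int,
    names: tuple[str, str, str] = ("model_training", "polytocous", "monotocous"),
) -> OverlapResult:
    """Three-set overlap with pairwise hypergeometric tests.

    ``universe`` is the number of genes eligible for all the DEG analyses
    being compared (the intersection of tested-gene families).
    """
    sets = {
        names[0]: set(training_degs),
        names[1]: set(poly_degs),
        names[2]: set(mono_degs),
    }
    regions = venn_regions(sets[names[0]], sets[names[1]], sets[names[2]])
    # pairwise tests: each within-sample set against the model-training set
    pairs = [(names[0], names[1]), (names[0], names[2])]
    rows = []
    for x, y in pairs:
        ov = len(sets[x] & sets[y])
        rows.append(
            {
                "pair": f"{x}|{y}",
                "overlap": ov,
                "size_1": len(sets[x]),
                "size_2": len(sets[y]),
                "universe": universe,
                "pvalue": hypergeom_overlap_test(ov, len(sets[x]), len(sets[y]), universe),
            }
        )
    return OverlapResult(
        regions=regions,
        set_sizes={k: len(v) for k, v in sets.items()},
        universe=universe,
        pairwise=pd.DataFrame(rows),
    )
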