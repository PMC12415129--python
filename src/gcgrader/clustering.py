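"""Leiden clustering of DEG-restricted profiles and purity pseudo-labeling.

Cells from both samples are pooled, a symmetrized k-nearest-neighbor graph
(Euclidean metric, k = 15) is built directly on the scaled DEG-restricted
profiles (the feature space is already low-dimensional, so no PCA), and
Leiden community detection optimizes RB-configuration modularity at
resolution 0.5 with a fixed seed.

Pseudo-labels follow cluster composition: only clusters with at least 75
cells are considered; a cluster with >= 80% of its cells from the
polytocous (high-fertility) sample is labeled FS, one with >= 80% from the
monotocous sample NFS, and everything else stays unlabeled.  Purity is
measured against the cluster's own size, the only reading consistent with
per-cluster percentage columns that sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.neighbors import NearestNeighbors

from .errors import InsufficientDataError, LabelingError, ParameterError, SchemaError, StateError
from .simulate import MONO, POLY, NORM_STATE_KEY

FS, NFS, UNLABELED = "FS", "NFS", "unlabeled"


@dataclass
class ClusterParams:
    n_neighbors: int = 15
    resolution: float = 0.5
    min_cells: int = 75
    purity_threshold: float = 0.80
    seed: int = 42

    def validate(self) -> None:
        if self.n_neighbors < 2:
            raise ParameterError("n_neighbors must be >= 2")
        if self.resolution <= 0:
            raise ParameterError("resolution must be > 0")
        if self.min_cells < 0:
            raise ParameterError("min_cells must be >= 0")
        if not 0.5 < self.purity_threshold <= 1.0:
            raise ParameterError("purity_threshold must lie in (0.5, 1]")


def knn_graph(X: np.ndarray, k: int) -> ig.Graph:
    """Symmetrized (union) kNN graph on rows of X, Euclidean metric."""
    n = X.shape[0]
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(X)
    _, idx = nn.kneighbors(X)
    edges = set()
    for i in range(n):
        for j in idx[i]:
            if i != j:
                edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def leiden_cluster(profiles: AnnData, params: ClusterParams | None = None) -> np.ndarray:
    """Per-cell cluster ids, 0-based, ordered by decreasing cluster size."""
    params = params or ClusterParams()
    params.validate()
    if profiles.uns.get(NORM_STATE_KEY) != "scaled":
        raise StateError("leiden_cluster requires profiles in 'scaled' state")
    n = profiles.n_obs
    if n < params.n_neighbors + 1:
        raise InsufficientDataError(
            f"{n} cells but n_neighbors={params.n_neighbors}; need at least "
            f"n_neighbors + 1 cells"
        )
    X = profiles.X.toarray() if sp.issparse(profiles.X) else np.asarray(profiles.X)
    g = knn_graph(X, params.n_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=params.resolution,
        seed=params.seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # relabel by decreasing size, ties broken by original community id
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    return np.asarray([remap[c] for c in raw], dtype=int)


def cluster_composition(
    assignment, origin, poly_label: str = POLY, mono_label: str = MONO
) -> pd.DataFrame:
    """Per-cluster origin counts and percentages, sorted by size descending.

    Percentages are 100 * count / total, rounded to 2 decimals.
    """
    assignment = np.asarray(assignment)
    origin = np.asarray(origin)
    if assignment.shape[0] != origin.shape[0]:
        raise SchemaError("assignment and origin must cover the same cells")
    rows = []
    for c in np.unique(assignment):
        mask = assignment == c
        total = int(mask.sum())
        n_poly = int((origin[mask] == poly_label).sum())
        n_mono = int((origin[mask] == mono_label).sum())
        if n_poly + n_mono != total:
            raise SchemaError(
                f"cluster {c}: origin tags other than "
                f"{poly_label!r}/{mono_label!r} present"
            )
        rows.append(
            {
                "cluster": int(c),
                "total": total,
                "n_polytocous": n_poly,
                "pct_polytocous": round(100.0 * n_poly / total, 2),
                "n_monotocous": n_mono,
                "pct_monotocous": round(100.0 * n_mono / total, 2),
            }
        )
    columns = [
        "cluster", "total", "n_polytocous", "pct_polytocous",
        "n_monotocous", "pct_monotocous",
    ]
    comp = pd.DataFrame(rows, columns=columns).sort_values(
        ["total", "cluster"], ascending=[False, True]
    )
    return comp.reset_index(drop=True)


def select_fs_nfs(
    composition: pd.DataFrame, params: ClusterParams | None = None
) -> pd.DataFrame:
    """Label clusters FS / NFS / unlabeled from their composition.

    FS: total >= min_cells and polytocous share >= purity_threshold;
    NFS: total >= min_cells and monotocous share >= purity_threshold.
    Shares are recomputed from counts (not the rounded percentage columns).
    """
    params = params or ClusterParams()
    params.validate()
    labels = []
    for _, row in composition.iterrows():
        total = int(row["total"])
        label = UNLABELED
        if total >= params.min_cells and total > 0:
            if row["n_polytocous"] / total >= params.purity_threshold:
                label = FS
            elif row["n_monotocous"] / total >= params.purity_threshold:
                label = NFS
        labels.append({"cluster": int(row["cluster"]), "label": label})
    return pd.DataFrame(labels)


def build_training_set(
    profiles: AnnData, assignment, labels: pd.DataFrame
) -> AnnData:
    """Cells of FS/NFS clusters with their pseudo-label, as a new AnnData.

    Cells in unlabeled clusters are dropped.  Raises
    :class:`LabelingError` when either class is absent — rerun clustering
    with a different resolution or purity threshold in that case.
    """
    assignment = np.asarray(assignment)
    if assignment.shape[0] != profiles.n_obs:
        raise SchemaError("assignment does not cover all cells")
    label_map = dict(zip(labels["cluster"].astype(int), labels["label"]))
    cell_labels = np.asarray([label_map.get(int(c), UNLABELED) for c in assignment])
    keep = cell_labels != UNLABELED
    n_fs = int((cell_labels == FS).sum())
    n_nfs = int((cell_labels == NFS).sum())
    if n_fs == 0 or n_nfs == 0:
        raise LabelingError(
            f"pseudo-labeling produced {n_fs} FS and {n_nfs} NFS cells; "
            "adjust the clustering resolution or purity threshold"
        )
    out = profiles[keep].copy()
    out.obs["pseudo_label"] = cell_labels[keep]
    out.obs["cluster"] = assignment[keep]
    out.uns["training_set_log"] = {"n_fs": n_fs, "n_nfs": n_nfs}
    out.uns[NORM_STATE_KEY] = profiles.uns.get(NORM_STATE_KEY, "scaled")
    return out


def resolution_sweep(
    profiles: AnnData,
    origin,
    resolutions,
    params: ClusterParams | None = None,
) -> pd.DataFrame:
    """Cluster at several resolutions and report enrichment summaries.

    For each resolution: number of clusters, number of cells in clusters
    passing the size floor, and the maximum single-origin purity reached —
    a helper for choosing the resolution that best enriches clusters for
    one sample origin.  No selection rule is imposed.
    """
    params = params or ClusterParams()
    rows = []
    for res in resolutions:
        p = ClusterParams(
            n_neighbors=params.n_neighbors,
            resolution=float(res),
            min_cells=params.min_cells,
            purity_threshold=params.purity_threshold,
            seed=params.seed,
        )
        assignment = leiden_cluster(profiles, p)
        comp = cluster_composition(assignment, origin)
        big = comp[comp["total"] >= p.min_cells]
        max_purity = (
            float(
                np.maximum(big["pct_polytocous"], big["pct_monotocous"]).max()
            )
            if len(big)
            else np.nan
        )
        labeled = select_fs_nfs(comp, p)
        n_labeled = int((labeled["label"] != UNLABELED).sum())
        rows.append(
            {
                "resolution": float(res),
                "n_clusters": int(comp.shape[0]),
                "n_clusters_min_cells": int(len(big)),
                "n_labeled_clusters": n_labeled,
                "max_purity_pct": max_purity,
            }
        )
    return pd.DataFrame(rows)


def cluster_params_to_dict(params: ClusterParams) -> dict:
    return asdict(params)
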