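"""Figure helpers (UMAP embeddings, three-set Venn diagram).

Plotting is a convenience layer over the results objects; nothing in the
analysis depends on it.
"""

from __future__ import annotations

import numpy as np


def plot_umap(profiles, color, ax=None, seed: int = 42, **scatter_kw):
    """2-D UMAP embedding of scaled profiles, colored by a label vector."""
    import matplotlib.pyplot as plt
    from umap import UMAP

    X = np.asarray(profiles, dtype=np.float64)
    emb = UMAP(random_state=seed).fit_transform(X)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    color = np.asarray(color)
    for value in np.unique(color):
        m = color == value
        ax.scatter(emb[m, 0], emb[m, 1], s=4, label=str(value), **scatter_kw)
    ax.set_xlabel("UMAP1")
    ax.set_ylabel("UMAP2")
    ax.legend(markerscale=3, frameon=False)
    return ax


def plot_venn(regions: dict[str, int], labels=("model-training", "polytocous", "monotocous"), ax=None):
    """Three-circle Venn diagram of DEG-set overlap region counts.

    ``regions`` uses the keys of :func:`gcgrader.quantify.venn_regions`.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    centers = [(-0.5, 0.3), (0.5, 0.3), (0.0, -0.55)]
    colors = ["tab:blue", "tab:orange", "tab:green"]
    for (cx, cy), col, lab in zip(centers, colors, labels):
        ax.add_patch(Circle((cx, cy), 1.0, alpha=0.3, color=col, label=lab))
    positions = {
        "a_only": (-1.0, 0.5),
        "b_only": (1.0, 0.5),
        "c_only": (0.0, -1.1),
        "ab_only": (0.0, 0.6),
        "ac_only": (-0.6, -0.3),
        "bc_only": (0.6, -0.3),
        "abc": (0.0, 0.0),
    }
    for key, (x, y) in positions.items():
        ax.text(x, y, str(regions.get(key, 0)), ha="center", va="center", fontsize=12)
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.2, 2.0)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="upper center", ncol=3, frameon=False)
    return ax
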