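"""Two-sample synthetic scRNA-seq generator with planted FS/NFS structure.

The generator emulates the study design this package targets: two granulosa
cell samples — one from a low-fertility (monotocous-like) and one from a
high-fertility (polytocous-like) animal — each a mixture of two latent cell
states, fertility-supporting (FS) and non-fertility-supporting (NFS).  A
chosen set of genes is differentially expressed between the states at a
planted log2 fold change, so every downstream stage (QC, differential
expression, cluster pseudo-labeling, classifier training, FS-percentage
estimation) can be validated against known ground truth without any
external download.

Count model
-----------
Counts are negative binomial: gene ``g`` has a baseline mean ``m_g`` drawn
log-normally around ``base_mean``; cell ``c`` has a multiplicative depth
factor with coefficient of variation ``depth_cv``; in FS cells the mean of a
planted gene is multiplied by ``2**(±planted_log2fc)``.  Planted genes are
split between up- and down-regulation in FS cells (``deg_up_fraction``), the
realistic shape of a differential-expression signature, which also keeps
library-size composition comparable between states.  Dropout is Bernoulli
zero-inflation, independent of expression level.  The per-cell mitochondrial
read fraction is an annotation drawn uniformly from ``mito_fraction_range``;
mitochondrial genes themselves are not simulated — the annotation is enough
to exercise the QC rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .errors import ParameterError

MONO = "monotocous"
POLY = "polytocous"

#: normalization-state key stored in ``adata.uns``
NORM_STATE_KEY = "norm_state"


@dataclass
class SimulationConfig:
    """Parameters of the two-sample generator.

    Defaults mirror the study conditions the package emulates: sample sizes
    1,588 (monotocous) and 1,536 (polytocous) cells, 44 planted
    differentially expressed genes, and a low/high planted FS share
    (10% / 85%) matching the expectation that polytocous ovaries are
    FS-dominated.
    """

    n_cells_per_sample: tuple[int, int] = (1588, 1536)
    n_genes: int = 2000
    fs_fraction: tuple[float, float] = (0.10, 0.85)
    n_deg: int = 44
    planted_log2fc: float = 2.5
    deg_up_fraction: float = 0.5
    base_mean: float = 20.0
    mean_log_sigma: float = 0.4
    dispersion: float = 0.1
    dropout_rate: float = 0.0
    depth_cv: float = 0.3
    mito_fraction_range: tuple[float, float] = (0.01, 0.15)
    seed: int = 42

    def validate(self) -> None:
        if len(self.n_cells_per_sample) != 2 or any(
            int(n) <= 0 for n in self.n_cells_per_sample
        ):
            raise ParameterError("n_cells_per_sample must be two positive integers")
        if self.n_genes <= 0:
            raise ParameterError("n_genes must be positive")
        if len(self.fs_fraction) != 2 or any(
            not 0.0 <= f <= 1.0 for f in self.fs_fraction
        ):
            raise ParameterError("fs_fraction components must lie in [0, 1]")
        if not 0 <= self.n_deg <= self.n_genes:
            raise ParameterError("n_deg must satisfy 0 <= n_deg <= n_genes")
        if self.planted_log2fc < 0:
            raise ParameterError("planted_log2fc must be nonnegative")
        if not 0.0 <= self.deg_up_fraction <= 1.0:
            raise ParameterError("deg_up_fraction must lie in [0, 1]")
        for name in ("base_mean", "mean_log_sigma", "dispersion"):
            if getattr(self, name) <= 0 and name != "mean_log_sigma":
                raise ParameterError(f"{name} must be > 0")
        if self.mean_log_sigma < 0:
            raise ParameterError("mean_log_sigma must be >= 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ParameterError("dropout_rate must lie in [0, 1]")
        if self.depth_cv < 0:
            raise ParameterError("depth_cv must be >= 0")
        lo, hi = self.mito_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ParameterError("mito_fraction_range must be an interval in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated dataset.

    ``cell_state`` maps sample name -> per-cell FS/NFS labels (aligned to
    the AnnData row order); ``deg_genes`` lists planted gene ids;
    ``log2fc`` carries the signed planted log2 fold change (FS over NFS)
    per planted gene.
    """

    cell_state: dict[str, pd.Series]
    deg_genes: list[str]
    log2fc: pd.Series
    config: SimulationConfig = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sample, states in self.cell_state.items():
            for cell, state in states.items():
                rows.append((cell, sample, state))
        return pd.DataFrame(rows, columns=["cell", "sample", "planted_state"])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (gamma-Poisson)."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    return rng.poisson(lam)


def generate_two_sample_dataset(
    config: SimulationConfig | None = None,
) -> tuple[dict[str, AnnData], GroundTruth]:
    """Simulate the monotocous/polytocous pair of count matrices.

    Returns a dict ``{"monotocous": AnnData, "polytocous": AnnData}`` over a
    shared gene set, plus the :class:`GroundTruth`.  Identical seeds give
    bit-identical output.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_ids(config.n_genes)
    # gene baseline means, log-normal around base_mean (mean-preserving)
    sig = config.mean_log_sigma
    gene_means = config.base_mean * np.exp(
        rng.normal(-0.5 * sig**2, sig, size=config.n_genes)
    )

    deg_idx = rng.choice(config.n_genes, size=config.n_deg, replace=False)
    deg_idx.sort()
    n_up = int(round(config.deg_up_fraction * config.n_deg))
    signs = np.full(config.n_deg, -1.0)
    up_pick = rng.permutation(config.n_deg)[:n_up]
    signs[up_pick] = 1.0
    planted_lfc = signs * config.planted_log2fc

    fold = np.ones(config.n_genes)
    fold[deg_idx] = 2.0**planted_lfc

    samples: dict[str, AnnData] = {}
    cell_state: dict[str, pd.Series] = {}
    sigma_d = np.sqrt(np.log1p(config.depth_cv**2))

    for sample, n_cells, fs_frac in zip(
        (MONO, POLY), config.n_cells_per_sample, config.fs_fraction
    ):
        n_cells = int(n_cells)
        n_fs = int(round(fs_frac * n_cells))
        states = np.array(["NFS"] * n_cells, dtype=object)
        states[rng.permutation(n_cells)[:n_fs]] = "FS"

        depth = np.exp(rng.normal(-0.5 * sigma_d**2, sigma_d, size=n_cells))
        mu = depth[:, None] * gene_means[None, :]
        is_fs = states == "FS"
        mu[is_fs] = mu[is_fs] * fold[None, :]

        counts = _nb_draw(rng, mu, config.dispersion)
        if config.dropout_rate > 0:
            keep = rng.random(counts.shape) >= config.dropout_rate
            counts = counts * keep
        mito = rng.uniform(*config.mito_fraction_range, size=n_cells)

        barcodes = [f"{sample[:4].upper()}_C{i:05d}" for i in range(1, n_cells + 1)]
        obs = pd.DataFrame(
            {
                "sample": pd.Categorical([sample] * n_cells, categories=[MONO, POLY]),
                "mito_frac": mito,
                "planted_state": states,
            },
            index=pd.Index(barcodes, name="cell"),
        )
        var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
        adata = AnnData(
            X=sp.csr_matrix(counts.astype(np.float64)), obs=obs, var=var
        )
        adata.uns[NORM_STATE_KEY] = "raw"
        samples[sample] = adata
        cell_state[sample] = pd.Series(states, index=obs.index, name="planted_state")

    truth = GroundTruth(
        cell_state=cell_state,
        deg_genes=[genes[i] for i in deg_idx],
        log2fc=pd.Series(planted_lfc, index=[genes[i] for i in deg_idx], name="log2fc"),
        config=config,
    )
    return samples, truth


def corrupt_for_qc(
    adata: AnnData,
    fractions: tuple[float, float, float],
    seed: int,
    min_total_counts: int = 10_000,
    min_genes: int = 1_500,
    max_mito_fraction: float = 0.25,
) -> tuple[AnnData, dict[str, list[str]]]:
    """Plant QC violations into a copy of ``adata``.

    ``fractions`` = (low_depth, few_genes, high_mito): disjoint random cell
    subsets of those sizes are modified so each cell fails exactly the
    designated retention rule (it may incidentally fail others).  Returns the
    corrupted copy and a dict rule -> corrupted cell ids (also stored in
    ``adata.uns['qc_corrupted']``).
    """
    fr = tuple(float(f) for f in fractions)
    if any(f < 0 or f > 1 for f in fr):
        raise ParameterError("fractions must lie in [0, 1]")
    if sum(fr) > 1:
        raise ParameterError("fractions must sum to at most 1")

    rng = np.random.default_rng(seed)
    out = adata.copy()
    n = out.n_obs
    order = rng.permutation(n)
    n_low, n_few, n_mito = (int(round(f * n)) for f in fr)
    idx_low = order[:n_low]
    idx_few = order[n_low : n_low + n_few]
    idx_mito = order[n_low + n_few : n_low + n_few + n_mito]

    X = out.X.tolil() if sp.issparse(out.X) else out.X

    # low depth: binomial-thin counts to ~half the retention threshold
    for i in idx_low:
        row = np.asarray(out.X[i].todense()).ravel() if sp.issparse(out.X) else out.X[i].copy()
        total = row.sum()
        target = max(1, min_total_counts // 2)
        if total > target:
            row = rng.binomial(row.astype(np.int64), target / total).astype(np.float64)
        X[i] = row
    # few genes: silence all but the top-expressed genes
    keep_genes = max(1, min(min_genes // 2, out.n_vars - 1))
    for i in idx_few:
        row = np.asarray(out.X[i].todense()).ravel() if sp.issparse(out.X) else out.X[i].copy()
        top = np.argsort(row)[::-1][:keep_genes]
        new = np.zeros_like(row)
        new[top] = row[top]
        X[i] = new

    out.X = X.tocsr() if sp.issparse(adata.X) else np.asarray(X)
    # high mito: push the annotation above the threshold
    mito = out.obs["mito_frac"].to_numpy().copy()
    mito[idx_mito] = rng.uniform(max_mito_fraction + 0.01, 1.0, size=len(idx_mito))
    out.obs["mito_frac"] = mito

    names = out.obs_names
    record = {
        "low_depth": [names[i] for i in idx_low],
        "few_genes": [names[i] for i in idx_few],
        "high_mito": [names[i] for i in idx_mito],
    }
    out.uns["qc_corrupted"] = {k: list(v) for k, v in record.items()}
    return out, record


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
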