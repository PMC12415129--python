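"""Random hyperparameter search over the published tuning grids."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from ..errors import ParameterError
from .config import ModelConfig, SearchSpace
from .engine import Adam
from .training import build_model, one_hot, _epoch_pass


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def sample_config(
    space: SearchSpace, rng: np.random.Generator, base: ModelConfig | None = None
) -> ModelConfig:
    """One draw: uniform on the discrete grids, log-uniform learning rate.

    A single dropout rate is drawn and applied to all three dropout sites,
    matching a one-rate tuning scheme.
    """
    base = base or ModelConfig()
    filters = int(rng.choice(_grid(*space.conv_filters)))
    gru = int(rng.choice(_grid(*space.gru_units)))
    dense = int(rng.choice(_grid(*space.dense_units)))
    dropout = float(rng.choice(np.round(_grid(*space.dropout), 10)))
    lo, hi = space.learning_rate
    lr = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
    return ModelConfig(
        conv_filters=filters,
        kernel_size=base.kernel_size,
        pool_size=base.pool_size,
        conv_dropout=dropout,
        gru_units=gru,
        gru_dropout=dropout,
        dense_units=dense,
        dense_dropout=dropout,
        n_classes=base.n_classes,
        learning_rate=lr,
        epochs=base.epochs,
        batch_size=base.batch_size,
        seed=base.seed,
        early_stopping=base.early_stopping,
        output_activation=base.output_activation,
    )


def hyperparameter_search(
    space: SearchSpace,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 42,
    trial_epochs: int = 4,
    base: ModelConfig | None = None,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Random search; each trial trains briefly and is scored on
    validation loss.  Deterministic under ``seed``.  Returns the best
    config (lowest validation loss) and the full trial log."""
    space.validate()
    if trial_epochs < 1:
        raise ParameterError("trial_epochs must be >= 1")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    idx = np.arange(len(y))
    idx_fit, idx_val = train_test_split(idx, test_size=0.3, stratify=y, random_state=seed)
    Xf, Yf = X[idx_fit], one_hot(y[idx_fit])
    Xv, Yv = X[idx_val], one_hot(y[idx_val])

    rows = []
    best_cfg, best_loss = None, np.inf
    for trial in range(space.budget):
        cfg = sample_config(space, rng, base=base)
        net = build_model(cfg, X.shape[1])
        opt = Adam(cfg.learning_rate)
        train_rng = np.random.default_rng(cfg.seed + trial)
        for _ in range(trial_epochs):
            _epoch_pass(net, opt, Xf, Yf, cfg.batch_size, train_rng)
        val_loss = net.loss(net.forward(Xv, training=False), Yv)
        rows.append(
            {
                "trial": trial,
                "conv_filters": cfg.conv_filters,
                "gru_units": cfg.gru_units,
                "dense_units": cfg.dense_units,
                "dropout": cfg.conv_dropout,
                "learning_rate": cfg.learning_rate,
                "val_loss": val_loss,
            }
        )
        if val_loss < best_loss:
            best_loss, best_cfg = val_loss, cfg
    return best_cfg, pd.DataFrame(rows)
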