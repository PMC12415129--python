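"""Training, evaluation, persistence and saliency for the hybrid classifier.

The labeled pseudo-training set is split 80/20 into training and test
partitions (stratified, seeded); 30% of the training portion is further
held out for validation.  Training runs up to ``epochs`` epochs at the
configured batch size with early stopping on validation loss (patience 3,
best weights restored).  FS is the positive class throughout: TP counts
FS cells correctly classified.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from ..errors import EvaluationError, ParameterError, TrainingError
from ..qc import GeneScaler
from .config import ModelConfig
from .engine import Adam, HybridNet

#: class order: column 0 = NFS, column 1 = FS (positive class)
CLASSES = ("NFS", "FS")


def one_hot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    Y = np.zeros((y.shape[0], n_classes))
    Y[np.arange(y.shape[0]), y] = 1.0
    return Y


@dataclass
class MetricsReport:
    """Confusion counts and the four headline metrics (percent)."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Accuracy, precision, recall, F1 from FS-positive confusion counts.

    Accuracy = (TP + TN) / total, Precision = TP / (TP + FP),
    Recall = TP / (TP + FN), F1 = 2 PR / (P + R); all reported as
    percentages.  Empty denominators yield 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise EvaluationError("labels and predictions must be equal-length, non-empty")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    total = tp + tn + fp + fn
    acc = 100.0 * (tp + tn) / total
    prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    rec = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2.0 * prec * rec / (prec + rec) if prec + rec else 0.0
    return MetricsReport(tp, tn, fp, fn, acc, prec, rec, f1)


@dataclass
class ModelBundle:
    """Everything needed to reuse a fitted classifier.

    Carries the architecture config, fitted weights, the persisted gene
    order (model input order), the per-gene scaler fitted on the training
    cells, the training history, and the identifiers of the held-out test
    partition (never touched during fitting).
    """

    config: ModelConfig
    input_length: int
    weights: dict[str, np.ndarray]
    gene_order: list[str]
    scaler: GeneScaler | None
    history: pd.DataFrame
    test_ids: list[str] = field(default_factory=list)
    classes: tuple[str, str] = CLASSES

    def make_net(self) -> HybridNet:
        net = HybridNet(self.config, self.input_length)
        net.load_state_dict(self.weights)
        return net

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.make_net().predict_proba(np.asarray(X, dtype=np.float64))

    # ----------------------------- persistence ----------------------- #
    def save(self, path: str | os.PathLike) -> None:
        path = str(path)
        os.makedirs(path, exist_ok=True)
        np.savez(os.path.join(path, "weights.npz"), **self.weights)
        meta = {
            "config": self.config.to_dict(),
            "input_length": self.input_length,
            "gene_order": list(self.gene_order),
            "scaler": self.scaler.to_dict() if self.scaler is not None else None,
            "history": self.history.to_dict(orient="list"),
            "test_ids": list(self.test_ids),
            "classes": list(self.classes),
        }
        with open(os.path.join(path, "bundle.json"), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ModelBundle":
        path = str(path)
        with open(os.path.join(path, "bundle.json")) as fh:
            meta = json.load(fh)
        with np.load(os.path.join(path, "weights.npz")) as npz:
            weights = {k: npz[k].copy() for k in npz.files}
        return cls(
            config=ModelConfig.from_dict(meta["config"]),
            input_length=int(meta["input_length"]),
            weights=weights,
            gene_order=list(meta["gene_order"]),
            scaler=GeneScaler.from_dict(meta["scaler"]) if meta["scaler"] else None,
            history=pd.DataFrame(meta["history"]),
            test_ids=list(meta["test_ids"]),
            classes=tuple(meta["classes"]),
        )


def build_model(config: ModelConfig, input_length: int) -> HybridNet:
    """An untrained network with seeded initial weights."""
    config.validate(input_length)
    return HybridNet(config, input_length, rng=np.random.default_rng(config.seed))


def _epoch_pass(
    net: HybridNet,
    opt: Adam,
    X: np.ndarray,
    Y: np.ndarray,
    batch_size: int,
    rng: np.random.Generator,
) -> float:
    order = rng.permutation(X.shape[0])
    losses = []
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        probs = net.forward(X[idx], training=True, rng=rng)
        losses.append(net.loss(probs, Y[idx]) * len(idx))
        net.backward_from_targets(Y[idx])
        opt.step(net.params, net.grads)
    return float(np.sum(losses) / len(order))


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig | None = None,
    gene_order: list[str] | None = None,
    scaler: GeneScaler | None = None,
    cell_ids: list[str] | None = None,
) -> tuple[ModelBundle, np.ndarray, np.ndarray]:
    """Fit the classifier; returns (bundle, X_test, y_test).

    ``X`` is the scaled profile matrix (cells x genes in ``gene_order``),
    ``y`` the binary labels (1 = FS).  The 20% test partition is split off
    first (stratified on y, seeded from the config), then 30% of the
    remaining training cells form the validation set monitored by early
    stopping.
    """
    config = config or ModelConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    config.validate(X.shape[1])
    if np.unique(y).size < 2:
        raise TrainingError("training set must contain both classes")
    cell_ids = list(cell_ids) if cell_ids is not None else [str(i) for i in range(len(y))]
    gene_order = list(gene_order) if gene_order is not None else [
        f"F{i}" for i in range(X.shape[1])
    ]

    idx = np.arange(len(y))
    idx_train, idx_test = train_test_split(
        idx, test_size=0.2, stratify=y, random_state=config.seed
    )
    idx_fit, idx_val = train_test_split(
        idx_train, test_size=0.3, stratify=y[idx_train], random_state=config.seed
    )
    Xf, Yf = X[idx_fit], one_hot(y[idx_fit], config.n_classes)
    Xv, Yv = X[idx_val], one_hot(y[idx_val], config.n_classes)

    net = build_model(config, X.shape[1])
    opt = Adam(config.learning_rate)
    rng = np.random.default_rng(config.seed)

    es = config.early_stopping
    best_loss, best_state, patience_left = np.inf, None, es.patience
    history = []
    for epoch in range(config.epochs):
        train_loss = _epoch_pass(net, opt, Xf, Yf, config.batch_size, rng)
        p_fit = net.predict_proba(Xf)
        p_val = net.predict_proba(Xv)
        val_probs = net.forward(Xv, training=False)
        val_loss = net.loss(val_probs, Yv)
        acc = float((p_fit.argmax(1) == Yf.argmax(1)).mean())
        val_acc = float((p_val.argmax(1) == Yv.argmax(1)).mean())
        history.append(
            {
                "epoch": epoch + 1,
                "loss": train_loss,
                "accuracy": acc,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        monitored = val_loss if es.monitor == "val_loss" else -val_acc
        if monitored < best_loss - 1e-12:
            best_loss = monitored
            best_state = net.state_dict()
            patience_left = es.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if es.restore_best and best_state is not None:
        net.load_state_dict(best_state)

    bundle = ModelBundle(
        config=config,
        input_length=X.shape[1],
        weights=net.state_dict(),
        gene_order=gene_order,
        scaler=scaler,
        history=pd.DataFrame(history),
        test_ids=[cell_ids[i] for i in idx_test],
    )
    return bundle, X[idx_test], y[idx_test]


def evaluate(bundle: ModelBundle, X_test: np.ndarray, y_test: np.ndarray) -> MetricsReport:
    """Hard arg-max predictions on the held-out test partition."""
    X_test = np.asarray(X_test, dtype=np.float64)
    y_test = np.asarray(y_test, dtype=int)
    if X_test.shape[0] == 0:
        raise EvaluationError("empty test set")
    probs = bundle.predict_proba(X_test)
    return compute_metrics(y_test, probs.argmax(axis=1))


def saliency(bundle: ModelBundle, profiles: np.ndarray) -> pd.DataFrame:
    """Mean |input gradient| of the predicted-class score, per gene.

    Scores are normalized to sum to 1 and returned descending.
    """
    if bundle.weights is None:
        raise ParameterError("bundle has no fitted weights")
    X = np.asarray(profiles, dtype=np.float64)
    net = bundle.make_net()
    probs = net.forward(X, training=False)
    pred = probs.argmax(axis=1)
    grads = net.input_gradient(X, pred)
    scores = np.abs(grads).mean(axis=0)
    total = scores.sum()
    if total > 0:
        scores = scores / total
    table = pd.DataFrame({"gene": bundle.gene_order, "saliency": scores})
    return table.sort_values("saliency", ascending=False).reset_index(drop=True)
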