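"""Architecture and training hyperparameters of the hybrid classifier."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from ..errors import ParameterError


@dataclass
class EarlyStopping:
    monitor: str = "val_loss"
    patience: int = 3
    restore_best: bool = True


@dataclass
class ModelConfig:
    """Defaults are the published architecture of the hybrid model:

    Conv1D(64 filters, kernel 2, ReLU) -> BatchNorm -> MaxPool(2) ->
    Dropout(0.2) -> GRU(64, dropout 0.2) -> LayerNorm -> Flatten ->
    Dense(192, ReLU) -> Dropout(0.2) -> Dense(2, sigmoid);
    categorical cross-entropy, Adam at 1e-3, 10 epochs, batch 32, seed 42.
    """

    conv_filters: int = 64
    kernel_size: int = 2
    pool_size: int = 2
    conv_dropout: float = 0.2
    gru_units: int = 64
    gru_dropout: float = 0.2
    dense_units: int = 192
    dense_dropout: float = 0.2
    n_classes: int = 2
    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 32
    seed: int = 42
    early_stopping: EarlyStopping = field(default_factory=EarlyStopping)
    #: "sigmoid" follows the published head (2 sigmoid units, probabilities
    #: renormalized to sum to 1 for thresholding); "softmax" is the
    #: alternative head behind a flag.
    output_activation: str = "sigmoid"
    bn_momentum: float = 0.9

    def validate(self, input_length: int | None = None) -> None:
        for name in ("conv_filters", "kernel_size", "pool_size", "gru_units",
                     "dense_units", "n_classes", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("conv_dropout", "gru_dropout", "dense_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ParameterError(f"{name} must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if self.output_activation not in ("sigmoid", "softmax"):
            raise ParameterError("output_activation must be 'sigmoid' or 'softmax'")
        if input_length is not None and self.kernel_size > input_length:
            raise ParameterError(
                f"kernel_size {self.kernel_size} exceeds input length {input_length}"
            )

    @classmethod
    def compact(cls, **overrides) -> "ModelConfig":
        """Capacity suited to short DEG signatures (roughly 5–20 genes).

        The full published capacity (64 filters / 64 GRU units / 192 dense)
        was tuned for a 44-gene signature; on much shorter signatures it
        overfits the pseudo-labeled prototypes and produces overconfident
        boundary cells.  These values lie on the same published tuning
        grids (filters/units in 16–128 step 4, dropout 0.1–0.5 step 0.1).
        """
        base = dict(
            conv_filters=16,
            gru_units=16,
            dense_units=32,
            conv_dropout=0.3,
            gru_dropout=0.3,
            dense_dropout=0.3,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        es = d.pop("early_stopping", None)
        cfg = cls(**d)
        if es is not None:
            cfg.early_stopping = EarlyStopping(**es)
        return cfg


@dataclass
class SearchSpace:
    """Random-search grids for hyperparameter tuning.

    Discrete grids: conv filters 16–128 step 4, GRU units 16–128 step 4,
    dense units 16–256 step 4, one shared dropout rate 0.1–0.5 step 0.1;
    learning rate sampled log-uniformly on [1e-4, 1e-2].
    """

    conv_filters: tuple[int, int, int] = (16, 128, 4)
    gru_units: tuple[int, int, int] = (16, 128, 4)
    dense_units: tuple[int, int, int] = (16, 256, 4)
    dropout: tuple[float, float, float] = (0.1, 0.5, 0.1)
    learning_rate: tuple[float, float] = (1e-4, 1e-2)
    budget: int = 10

    def validate(self) -> None:
        if self.budget < 1:
            raise ParameterError("budget must be >= 1")
        for name in ("conv_filters", "gru_units", "dense_units", "dropout"):
            lo, hi, step = getattr(self, name)
            if not (lo <= hi and step > 0):
                raise ParameterError(f"invalid grid for {name}")
        lo, hi = self.learning_rate
        if not 0 < lo <= hi:
            raise ParameterError("invalid learning_rate range")
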