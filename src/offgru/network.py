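"""The off-target classifier: Inception front end + stacked BiGRU.

The full model reads a 24-position encoded sgRNA-DNA pair, passes it
through four parallel length-preserving convolutions (widths 1, 2, 3, 5;
10 filters each) whose outputs are concatenated along the channel axis,
then through a stack of three bidirectional GRU layers (30, 20, 10 units,
all returning per-position outputs), and finally through dense layers of
128 and 64 ReLU units (dropout 0.35 after each) into two sigmoid output
neurons scoring the on- and off-target propensities.

Two ablation variants drop one of the two feature extractors, and a much
smaller ``student`` variant (single width-3 convolution, one BiGRU of 10
units, dense 32) is used for knowledge distillation on the 16-channel
base-pair encoding.

Training uses Adam (default learning rate 1e-4), balanced bootstrap
batches of 256 (half positives, half negatives, drawn with replacement),
and the dice loss by default; 30 epochs is the default budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .data import balanced_bootstrap_batches
from .losses import TrainingLoss, DistillationLoss

VARIANTS = ("full", "no_inception", "no_bigru", "student")


@dataclass
class ModelConfig:
    """Architecture and optimizer hyperparameters."""

    conv_kernel_widths: list[int] = field(default_factory=lambda: [1, 2, 3, 5])
    conv_filters: int = 10
    bigru_units: list[int] = field(default_factory=lambda: [30, 20, 10])
    dense_units: list[int] = field(default_factory=lambda: [128, 64])
    dropout_rate: float = 0.35
    learning_rate: float = 1e-4
    input_shape: tuple[int, int] = (24, 7)
    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; valid: {', '.join(VARIANTS)}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if any(u < 1 for u in self.bigru_units + self.dense_units) or self.conv_filters < 1:
            raise ValueError("all unit counts must be >= 1")
        self.input_shape = tuple(self.input_shape)
        if self.input_shape[1] not in (7, 16):
            raise ValueError("input channels must be 7 (teacher) or 16 (student)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_shape"] = list(self.input_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    @classmethod
    def student(cls, input_channels: int = 16) -> "ModelConfig":
        """Reduced student architecture for distillation (~10x fewer weights).

        The small network tolerates (and needs) a larger Adam step than
        the full model to converge within the same epoch budget.
        """
        return cls(
            conv_kernel_widths=[3],
            conv_filters=10,
            bigru_units=[10],
            dense_units=[32],
            learning_rate=1e-3,
            input_shape=(24, input_channels),
            variant="student",
        )


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 256
    loss: str = "dice"
    verbose: bool = False


class ModelHandle:
    """A built (possibly trained) model plus its config and seed bookkeeping.

    One integer seed fans out (via ``numpy.random.SeedSequence``) to weight
    initialisation, dropout masks, and the balanced batch sampler, so a
    rebuild + retrain with the same seed reproduces predictions exactly.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        init_ss, drop_ss, sample_ss = np.random.SeedSequence(self.seed).spawn(3)
        self._dropout_rng = np.random.default_rng(drop_ss)
        self._sampler_rng = np.random.default_rng(sample_ss)
        self.net = _build_network(config, np.random.default_rng(init_ss),
                                  self._dropout_rng)
        self.history: list[float] = []

    # ------------------------------------------------------------------
    @property
    def parameter_count(self) -> int:
        return self.net.parameter_count

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Probabilities, shape (n, 2): column 0 on-target, column 1 off-target."""
        batch = np.asarray(batch, dtype=float)
        expected = self.config.input_shape
        if batch.ndim != 3 or batch.shape[1:] != expected:
            raise ValueError(
                f"batch shape {batch.shape} incompatible with model input "
                f"(n, {expected[0]}, {expected[1]})"
            )
        return self.net.predict(batch)

    def predict_scores(self, batch: np.ndarray) -> np.ndarray:
        """Off-target score vector (second output column)."""
        return self.predict(batch)[:, 1]

    # ------------------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        weights = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        np.savez(directory / "weights.npz", **weights)
        meta = {"config": self.config.to_dict(), "seed": self.seed,
                "history": self.history}
        (directory / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelHandle":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        handle = cls(ModelConfig.from_dict(meta["config"]), seed=meta["seed"])
        with np.load(directory / "weights.npz") as npz:
            handle.net.set_weights([npz[f"w{i}"] for i in range(len(npz.files))])
        handle.history = list(meta.get("history", []))
        return handle


def _build_network(cfg: ModelConfig, init_rng: np.random.Generator,
                   dropout_rng: np.random.Generator) -> nn.Network:
    T, channels = cfg.input_shape
    layers: list[nn.Layer] = []
    width = channels

    use_inception = cfg.variant in ("full", "no_bigru", "student")
    use_bigru = cfg.variant in ("full", "no_inception", "student")

    if use_inception:
        inception = nn.Inception(cfg.conv_kernel_widths, channels,
                                 cfg.conv_filters, init_rng)
        layers.append(inception)
        width = inception.out_channels
    if use_bigru:
        for units in cfg.bigru_units:
            gru = nn.BiGRU(units, width, init_rng)
            layers.append(gru)
            width = gru.out_channels
    layers.append(nn.Flatten())
    features = T * width
    for units in cfg.dense_units:
        layers.append(nn.Dense(features, units, init_rng, activation="relu"))
        layers.append(nn.Dropout(cfg.dropout_rate, dropout_rng))
        features = units
    layers.append(nn.Dense(features, 2, init_rng, activation="sigmoid"))
    return nn.Network(layers)


def build_model(config: ModelConfig | None = None, seed: int = 0) -> ModelHandle:
    """Build an untrained model of the requested variant."""
    return ModelHandle(config or ModelConfig(), seed=seed)


def expected_parameter_count(cfg: ModelConfig) -> int:
    """Closed-form parameter count, independent of the layer implementation.

    conv branch: width*in*filters + filters; bidirectional GRU layer:
    2*3*(u*(u+i) + 2u); dense: in*units + units.
    """
    T, channels = cfg.input_shape
    total = 0
    width = channels
    if cfg.variant in ("full", "no_bigru", "student"):
        total += sum(w * channels * cfg.conv_filters + cfg.conv_filters
                     for w in cfg.conv_kernel_widths)
        width = cfg.conv_filters * len(cfg.conv_kernel_widths)
    if cfg.variant in ("full", "no_inception", "student"):
        for u in cfg.bigru_units:
            total += 2 * 3 * (u * (u + width) + 2 * u)
            width = 2 * u
    features = T * width
    for u in cfg.dense_units + [2]:
        total += features * u + u
        features = u
    return total


def train(model: ModelHandle, X: np.ndarray, y: np.ndarray,
          train_cfg: TrainConfig | None = None,
          teacher_scores: np.ndarray | None = None,
          kd_alpha: float = 0.2, kd_temperature: float = 1.0) -> ModelHandle:
    """Train in place with balanced bootstrap batches and Adam.

    When ``teacher_scores`` (per-record soft off-target probabilities from
    a teacher model) is given, the distillation objective
    ``alpha*SL + (1-alpha)*DL`` replaces the plain loss.

    Raises ``ValueError`` if either class is absent: balanced sampling is
    then impossible.
    """
    cfg = train_cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of records")

    if teacher_scores is None:
        loss_fn = TrainingLoss(cfg.loss)
    else:
        teacher_scores = np.asarray(teacher_scores, dtype=float).ravel()
        if teacher_scores.shape[0] != y.shape[0]:
            raise ValueError("teacher_scores length must match the dataset")
        loss_fn = DistillationLoss(cfg.loss, alpha=kd_alpha,
                                   temperature=kd_temperature)

    optimizer = nn.Adam(model.net.parameters(), lr=model.config.learning_rate)
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for idx in balanced_bootstrap_batches(y, cfg.batch_size,
                                              model._sampler_rng):
            probs = model.net.forward(X[idx], train=True)
            if teacher_scores is None:
                value, dP = loss_fn(y[idx], probs)
            else:
                value, dP = loss_fn(y[idx], probs, teacher_scores[idx])
            model.net.zero_grad()
            model.net.backward(dP)
            optimizer.step(model.net.gradients())
            epoch_losses.append(value)
        model.history.append(float(np.mean(epoch_losses)))
        if cfg.verbose:
            print(f"epoch {epoch + 1:3d}/{cfg.epochs}  loss {model.history[-1]:.4f}")
    return model


def predict(model: ModelHandle, batch: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`ModelHandle.predict`."""
    return model.predict(batch)
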