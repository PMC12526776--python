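"""The baseline and final 1D CNN surface classifiers.

Two architectures over (frames x channels) segments:

* baseline — [conv -> ReLU -> max-pool(2) -> dropout] x L, then
  flatten -> dense -> ReLU -> dense(2) -> softmax;
* final — each conv block is conv -> batch-norm -> ReLU -> dropout
  (batch normalization stabilizes and speeds up training), same dense
  head.

Hyperparameters live on a validated grid: 1-4 conv layers, 32-256
filters in steps of 32, kernels 3-5, dropout 0-0.5 in steps of 0.1,
learning rate 1e-4 to 1e-2, Adam/RMSprop/SGD, batch sizes
{50, 100, 200, 300}.  Training uses early stopping on validation loss
(default patience 50, epoch cap 500) and restores the best-validation
epoch.  ``tune`` runs a seeded uniform random search over the grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import nn
from .preprocessing import SegmentTensor
from .splitting import SplitSpec

FILTER_GRID = tuple(range(32, 257, 32))
KERNEL_GRID = (3, 4, 5)
DROPOUT_GRID = tuple(round(0.1 * i, 1) for i in range(6))
BATCH_GRID = (50, 100, 200, 300)
OPTIMIZER_GRID = ("adam", "rmsprop", "sgd")
LR_RANGE = (1e-4, 1e-2)
REGULARIZATION_GRID = ("none", "l1", "l2", "l1_l2")


class ConfigError(ValueError):
    """A hyperparameter outside the tuning grid."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one classifier, validated against the grid."""

    n_conv_layers: int = 2
    filters: tuple[int, ...] = (64, 64)
    kernel_size: int = 5
    dropout: float = 0.2
    batch_norm_flag: bool = True
    dense_units: int = 100
    #: conservative default: segments enter at raw physical scale
    #: (tens of m/s^2) when amplitude normalization is off, and larger
    #: rates can kill the ReLU stack in the first few updates.
    learning_rate: float = 3e-4
    optimizer: str = "adam"
    batch_size: int = 200
    max_epochs: int = 500
    patience: int = 50
    #: minimum validation-loss drop that counts as an improvement for
    #: early stopping; guards against patience resets from float jitter.
    min_delta: float = 1e-4
    regularization: str = "none"
    reg_ratio: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_conv_layers <= 4:
            raise ConfigError(
                f"n_conv_layers must be 1-4, got {self.n_conv_layers}"
            )
        if len(self.filters) != self.n_conv_layers:
            raise ConfigError(
                f"filters must list one count per conv layer "
                f"({self.n_conv_layers}), got {self.filters}"
            )
        for f in self.filters:
            if f not in FILTER_GRID:
                raise ConfigError(
                    f"filters must come from {FILTER_GRID[0]}..{FILTER_GRID[-1]} "
                    f"step 32, got {f}"
                )
        if self.kernel_size not in KERNEL_GRID:
            raise ConfigError(f"kernel_size must be in {KERNEL_GRID}")
        if not any(abs(self.dropout - d) < 1e-9 for d in DROPOUT_GRID):
            raise ConfigError(
                f"dropout must be in {DROPOUT_GRID}, got {self.dropout}"
            )
        if self.dense_units < 1:
            raise ConfigError("dense_units must be >= 1")
        if not LR_RANGE[0] <= self.learning_rate <= LR_RANGE[1]:
            raise ConfigError(
                f"learning_rate must lie in [{LR_RANGE[0]}, {LR_RANGE[1]}]"
            )
        if self.optimizer not in OPTIMIZER_GRID:
            raise ConfigError(f"optimizer must be one of {OPTIMIZER_GRID}")
        if self.batch_size not in BATCH_GRID:
            raise ConfigError(f"batch_size must be in {BATCH_GRID}")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.min_delta < 0:
            raise ConfigError("min_delta must be >= 0")
        if self.regularization not in REGULARIZATION_GRID:
            raise ConfigError(
                f"regularization must be one of {REGULARIZATION_GRID}"
            )
        if self.reg_ratio < 0:
            raise ConfigError("reg_ratio must be >= 0")

    @property
    def l1(self) -> float:
        return self.reg_ratio if self.regularization in ("l1", "l1_l2") else 0.0

    @property
    def l2(self) -> float:
        return self.reg_ratio if self.regularization in ("l2", "l1_l2") else 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filters"] = list(self.filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "filters" in d:
            d["filters"] = tuple(d["filters"])
        return cls(**d)


def _build(
    input_frames: int,
    input_channels: int,
    config: ModelConfig,
    batch_norm: bool,
    pool: bool,
) -> nn.Network:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    layers: list[nn.Layer] = []
    t, c = input_frames, input_channels
    for f in config.filters:
        layers.append(nn.Conv1D(c, f, config.kernel_size, rng))
        t = t - config.kernel_size + 1
        if t < 1:
            raise ConfigError(
                f"input of {input_frames} frames too short for "
                f"{config.n_conv_layers} conv layers with kernel "
                f"{config.kernel_size}"
            )
        c = f
        if batch_norm:
            layers.append(nn.BatchNorm1D(f))
        layers.append(nn.ReLU())
        if pool:
            layers.append(nn.MaxPool1D(2))
            t //= 2
            if t < 1:
                raise ConfigError("input too short for the pooling stack")
        if config.dropout > 0:
            layers.append(nn.Dropout(config.dropout))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(t * c, config.dense_units, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(config.dense_units, 2, rng))
    return nn.Network(layers)


def build_baseline(
    input_frames: int, input_channels: int, config: ModelConfig | None = None
) -> nn.Network:
    """Preliminary-testing architecture: conv/ReLU/max-pool/dropout blocks."""
    config = config or ModelConfig(batch_norm_flag=False)
    return _build(input_frames, input_channels, config, batch_norm=False, pool=True)


def build_final(
    input_frames: int, input_channels: int, config: ModelConfig | None = None
) -> nn.Network:
    """Final architecture: conv/batch-norm/ReLU/dropout blocks.

    Batch normalization can be toggled off through the config flag, which
    reduces each block to conv/ReLU/dropout.
    """
    config = config or ModelConfig()
    return _build(
        input_frames,
        input_channels,
        config,
        batch_norm=config.batch_norm_flag,
        pool=False,
    )


@dataclass
class TrainedModel:
    """A fitted network plus its training record.

    input_mean/input_sd are per-channel standardization constants fitted
    on the training set and applied to every batch the model sees; they
    make optimization insensitive to the physical scale of the inputs
    (tens of m/s^2 raw vs order 1 after amplitude normalization) without
    touching the between-segment amplitude structure.
    """

    network: nn.Network
    config: ModelConfig
    history: dict[str, list[float]]
    stopped_epoch: int
    best_epoch: int
    input_frames: int
    input_channels: int
    input_mean: np.ndarray | None = None
    input_sd: np.ndarray | None = None

    def standardize(self, values: np.ndarray) -> np.ndarray:
        if self.input_mean is None:
            return values
        return (values - self.input_mean) / self.input_sd

    @property
    def architecture(self) -> list[str]:
        return self.network.describe()


def _check_tensor_split(tensor: SegmentTensor, split: SplitSpec) -> None:
    if split.n_segments != tensor.n_segments:
        raise ValueError(
            f"split covers {split.n_segments} segments, tensor has "
            f"{tensor.n_segments}"
        )
    for name, idx in split.sets().items():
        if len(idx) == 0:
            raise ValueError(f"split set {name!r} is empty")
    if not set(np.unique(tensor.labels)) <= {0, 1}:
        raise ValueError("labels must be binary (grass=0, asphalt=1)")


def train(
    model: nn.Network,
    tensor: SegmentTensor,
    split: SplitSpec,
    config: ModelConfig,
) -> TrainedModel:
    """Fit by mini-batch cross-entropy with early stopping.

    Stops once validation loss has not improved for ``patience``
    consecutive epochs (or at ``max_epochs``) and restores the
    parameters of the best-validation-loss epoch.
    """
    _check_tensor_split(tensor, split)
    x_train = tensor.values[split.train]
    y_train = tensor.labels[split.train]
    x_val = tensor.values[split.val]
    y_val = tensor.labels[split.val]

    # Per-channel standardization fitted on the training set only.
    input_mean = x_train.mean(axis=(0, 1), dtype=np.float64).astype(np.float32)
    input_sd = x_train.std(axis=(0, 1), dtype=np.float64).astype(np.float32)
    input_sd[input_sd == 0] = 1.0
    x_train = (x_train - input_mean) / input_sd
    x_val = (x_val - input_mean) / input_sd

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    optimizer = nn.make_optimizer(config.optimizer, config.learning_rate)

    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
    }
    best_loss = np.inf
    best_state = model.get_state()
    best_epoch = 0
    since_best = 0
    stopped = config.max_epochs

    n = len(x_train)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, acc = model.loss_and_grads(
                x_train[idx], y_train[idx], rng, l1=config.l1, l2=config.l2
            )
            optimizer.step(model)
            losses.append(loss)
            accs.append(acc)
        val_loss, val_acc = model.evaluate(x_val, y_val)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(float(np.mean(accs)))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)

        if val_loss < best_loss - config.min_delta:
            best_loss = val_loss
            best_state = model.get_state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                stopped = epoch
                break

    model.set_state(best_state)
    return TrainedModel(
        network=model,
        config=config,
        history=history,
        stopped_epoch=min(stopped, len(history["loss"])),
        best_epoch=best_epoch,
        input_frames=tensor.frames,
        input_channels=len(tensor.channel_names),
        input_mean=input_mean,
        input_sd=input_sd,
    )


def predict(
    trained: TrainedModel, tensor: SegmentTensor | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and hard labels for a batch of segments.

    Ties at 0.5 resolve to class 0 (grass).
    """
    values = tensor.values if isinstance(tensor, SegmentTensor) else np.asarray(tensor)
    if values.ndim != 3 or values.shape[1:] != (
        trained.input_frames,
        trained.input_channels,
    ):
        raise ValueError(
            f"expected segments of shape (*, {trained.input_frames}, "
            f"{trained.input_channels}), got {values.shape}"
        )
    probs = trained.network.predict_proba(trained.standardize(values))
    labels = probs.argmax(axis=1)  # argmax takes the first maximum: ties -> 0
    return probs, labels


@dataclass(frozen=True)
class SearchSpace:
    """The random-search grid (defaults: the full tuning grid)."""

    n_conv_layers: tuple[int, ...] = (1, 2, 3, 4)
    filters: tuple[int, ...] = FILTER_GRID
    kernel_size: tuple[int, ...] = KERNEL_GRID
    dropout: tuple[float, ...] = DROPOUT_GRID
    optimizer: tuple[str, ...] = OPTIMIZER_GRID
    batch_size: tuple[int, ...] = BATCH_GRID
    learning_rate: tuple[float, float] = LR_RANGE
    regularization: tuple[str, ...] = ("none",)

    def __post_init__(self) -> None:
        for name in (
            "n_conv_layers", "filters", "kernel_size", "dropout",
            "optimizer", "batch_size", "regularization",
        ):
            if not getattr(self, name):
                raise ConfigError(f"search space field {name!r} is empty")

    def sample(self, rng: np.random.Generator, base: ModelConfig) -> ModelConfig:
        """One uniform draw from the grid (log-uniform learning rate)."""
        n_layers = int(rng.choice(self.n_conv_layers))
        lr = float(
            np.exp(
                rng.uniform(
                    np.log(self.learning_rate[0]), np.log(self.learning_rate[1])
                )
            )
        )
        return replace(
            base,
            n_conv_layers=n_layers,
            filters=tuple(int(rng.choice(self.filters)) for _ in range(n_layers)),
            kernel_size=int(rng.choice(self.kernel_size)),
            dropout=float(rng.choice(self.dropout)),
            optimizer=str(rng.choice(self.optimizer)),
            batch_size=int(rng.choice(self.batch_size)),
            learning_rate=lr,
            regularization=str(rng.choice(self.regularization)),
        )


@dataclass
class TuneTrial:
    config: ModelConfig
    val_accuracy: float
    val_loss: float
    stopped_epoch: int


def tune(
    search_space: SearchSpace,
    tensor: SegmentTensor,
    split: SplitSpec,
    budget: int,
    seed: int = 0,
    base_config: ModelConfig | None = None,
    architecture: str = "final",
) -> tuple[ModelConfig, list[TuneTrial]]:
    """Seeded uniform random search over the hyperparameter grid.

    Each of ``budget`` trials draws a config from its own sub-stream of
    ``seed`` (so larger budgets extend, never reshuffle, smaller ones),
    trains with early stopping, and scores validation accuracy.  Returns
    the best config — ties broken by lower validation loss, then earlier
    trial — plus the full log.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    base = base_config or ModelConfig()
    builder = build_final if architecture == "final" else build_baseline
    trials: list[TuneTrial] = []
    for i in range(budget):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        config = search_space.sample(rng, base)
        config = replace(config, seed=int(rng.integers(2**31)))
        model = builder(tensor.frames, len(tensor.channel_names), config)
        fitted = train(model, tensor, split, config)
        best = int(np.argmin(fitted.history["val_loss"]))
        trials.append(
            TuneTrial(
                config=config,
                val_accuracy=fitted.history["val_accuracy"][best],
                val_loss=fitted.history["val_loss"][best],
                stopped_epoch=fitted.stopped_epoch,
            )
        )
    order = sorted(
        range(len(trials)),
        key=lambda i: (-trials[i].val_accuracy, trials[i].val_loss, i),
    )
    return trials[order[0]].config, trials
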