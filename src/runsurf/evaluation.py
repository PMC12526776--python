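"""Classification metrics and the factorial experiment harness.

Metrics are computed per surface class (grass, asphalt) from a 2x2
confusion matrix — precision, recall, F1 — plus overall accuracy in
percent.  ``run_experiment`` crosses the pipeline factors (signal type,
sensor combination, segmentation mode, normalization, split protocol)
and trains/evaluates one classifier per cell per seed, emitting a
long-format results table for directional comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .layout import (
    COMBINATION_NAMES,
    KNEE_CHANNELS,
    SIGNAL_TYPES,
    SensorCombination,
)
from .model import ModelConfig, TrainedModel, build_baseline, build_final, predict, train
from .preprocessing import (
    SURFACE_CODES,
    assemble_tensor,
    normalize_amplitude,
    select_channels,
)
from .segmentation import TrimPolicy, segment_trials
from .splitting import (
    DEFAULT_FRACTIONS,
    split_subject_dependent,
    split_subject_wise,
)
from .synthetic import TrialRecording

CLASS_NAMES = ("grass", "asphalt")


class ZeroDenominatorWarning(UserWarning):
    """A precision/recall denominator was zero; the metric is reported as 0."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; rows are true class (grass, asphalt), columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a 2x2 matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    valid = set(SURFACE_CODES.values())
    foreign = (set(np.unique(y_true)) | set(np.unique(y_pred))) - valid
    if foreign:
        raise ValueError(f"labels must be in {sorted(valid)}; got extra {foreign}")
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class MetricsBlock:
    """Per-class precision/recall/F1 and overall accuracy (%)."""

    precision: Mapping[str, float]
    recall: Mapping[str, float]
    f1: Mapping[str, float]
    accuracy_pct: float


def metrics(cm: ConfusionMatrix) -> MetricsBlock:
    """Per-class precision, recall, F1 and overall accuracy from counts.

    Zero-denominator cases (a class never predicted, or absent from the
    truth) yield a 0 metric with a warning, so degenerate all-one-class
    predictions stay reportable.
    """
    counts = cm.counts
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    precision, recall, f1 = {}, {}, {}
    for code, name in enumerate(CLASS_NAMES):
        tp = float(counts[code, code])
        predicted = float(counts[:, code].sum())
        actual = float(counts[code, :].sum())
        if predicted == 0 or actual == 0:
            warnings.warn(
                f"zero denominator for class {name!r}; metric set to 0",
                ZeroDenominatorWarning,
                stacklevel=2,
            )
        precision[name] = tp / predicted if predicted else 0.0
        recall[name] = tp / actual if actual else 0.0
        f1[name] = f1_score(precision[name], recall[name])
    accuracy = float(np.trace(counts)) / cm.total * 100.0
    return MetricsBlock(
        precision=precision, recall=recall, f1=f1, accuracy_pct=accuracy
    )


@dataclass
class EvalReport:
    """Metrics plus the full configuration that produced them."""

    cm: ConfusionMatrix
    metrics: MetricsBlock
    descriptor: dict
    stopped_epoch: int | None = None

    def to_row(self) -> dict:
        row = dict(self.descriptor)
        for name in CLASS_NAMES:
            row[f"precision_{name}"] = round(self.metrics.precision[name], 3)
            row[f"recall_{name}"] = round(self.metrics.recall[name], 3)
            row[f"f1_{name}"] = round(self.metrics.f1[name], 3)
        row["accuracy_pct"] = self.metrics.accuracy_pct
        row["stopped_epoch"] = self.stopped_epoch
        row.update(
            {
                f"cm_{t}_{p}": int(self.cm.counts[i, j])
                for i, t in enumerate(CLASS_NAMES)
                for j, p in enumerate(CLASS_NAMES)
            }
        )
        return row


def evaluate_model(
    trained: TrainedModel, tensor, indices: np.ndarray, descriptor: dict
) -> EvalReport:
    """Predict a held-out index set and compile the report."""
    subset = tensor.subset(indices)
    _, y_pred = predict(trained, subset)
    cm = confusion(subset.labels, y_pred)
    return EvalReport(
        cm=cm,
        metrics=metrics(cm),
        descriptor=descriptor,
        stopped_epoch=trained.stopped_epoch,
    )


FACTOR_LEVELS = {
    "signal_type": SIGNAL_TYPES,
    "combination": COMBINATION_NAMES,
    "segmentation": ("cycles", "window"),
    "normalization": (False, True),
    "split": ("subject_wise", "subject_dependent"),
}

DEFAULT_GRID = {
    "signal_type": ["acceleration"],
    "combination": ["feet"],
    "segmentation": ["cycles"],
    "normalization": [False],
    "split": ["subject_dependent"],
}


def _validate_grid(grid: Mapping[str, Sequence]) -> dict[str, list]:
    if not grid:
        raise ValueError("empty experiment grid")
    full = dict(DEFAULT_GRID)
    for factor, levels in grid.items():
        if factor not in FACTOR_LEVELS:
            raise ValueError(
                f"unknown factor {factor!r}; expected {tuple(FACTOR_LEVELS)}"
            )
        levels = list(levels)
        if not levels:
            raise ValueError(f"factor {factor!r} has no levels")
        bad = [lv for lv in levels if lv not in FACTOR_LEVELS[factor]]
        if bad:
            raise ValueError(
                f"unknown level(s) {bad} for factor {factor!r}; "
                f"expected {FACTOR_LEVELS[factor]}"
            )
        full[factor] = levels
    return full


def run_experiment(
    grid: Mapping[str, Sequence],
    trials: Sequence[TrialRecording],
    base_config: ModelConfig | None = None,
    seeds: Sequence[int] = (0,),
    architecture: str = "baseline",
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    target_frames: int = 100,
    window_s: float = 4.0,
    trim_policy: TrimPolicy = TrimPolicy(),
) -> pd.DataFrame:
    """Train and evaluate one model per grid cell per seed.

    Factors not named in ``grid`` stay at the default pipeline (gait
    cycles, no normalization, feet acceleration, subject-dependent
    split).  Segmentation work is cached across cells.  Returns a
    long-format table: one row per cell x seed with the full
    configuration, per-class metrics, accuracy and confusion counts.
    """
    full_grid = _validate_grid(grid)
    if architecture not in ("baseline", "final"):
        raise ValueError(f"unknown architecture {architecture!r}")
    base_config = base_config or ModelConfig()
    builder = build_final if architecture == "final" else build_baseline

    seg_cache: dict[tuple[str, bool], list] = {}

    def segments_for(mode: str, normalize: bool):
        key = (mode, normalize)
        if key not in seg_cache:
            data = trials
            if normalize:
                # Per-trial amplitude statistics, applied before cutting;
                # the knee angle stays in degrees for event detection.
                data = [
                    normalize_amplitude(t, exclude_channels=KNEE_CHANNELS)
                    if not t.dropped_flag
                    else t
                    for t in trials
                ]
            segs, _report = segment_trials(
                data,
                mode=mode,
                target_frames=target_frames,
                window_s=window_s,
                trim_policy=trim_policy,
            )
            seg_cache[key] = segs
        return seg_cache[key]

    rows = []
    for segmentation in full_grid["segmentation"]:
        for normalization in full_grid["normalization"]:
            base_segments = segments_for(segmentation, normalization)
            for signal_type in full_grid["signal_type"]:
                for combination in full_grid["combination"]:
                    combo = SensorCombination(combination, signal_type)
                    segs = select_channels(base_segments, combo)
                    tensor = assemble_tensor(segs)
                    for protocol in full_grid["split"]:
                        for seed in seeds:
                            if protocol == "subject_wise":
                                split = split_subject_wise(
                                    tensor.subjects, fractions, seed
                                )
                            else:
                                split = split_subject_dependent(
                                    tensor.n_segments,
                                    fractions,
                                    seed,
                                    stratify_by_surface=True,
                                    surface_labels=tensor.labels,
                                )
                            config = replace(base_config, seed=seed)
                            model = builder(
                                tensor.frames, len(tensor.channel_names), config
                            )
                            fitted = train(model, tensor, split, config)
                            descriptor = {
                                "signal_type": signal_type,
                                "combination": combination,
                                "segmentation": segmentation,
                                "normalization": normalization,
                                "split": protocol,
                                "architecture": architecture,
                                "seed": seed,
                            }
                            report = evaluate_model(
                                fitted, tensor, split.test, descriptor
                            )
                            rows.append(report.to_row())
    return pd.DataFrame(rows)


def summarize_experiment(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of accuracy per grid cell across seeds."""
    factors = [
        c
        for c in ("signal_type", "combination", "segmentation",
                  "normalization", "split", "architecture")
        if c in results.columns
    ]
    grouped = results.groupby(factors, dropna=False)["accuracy_pct"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    return out.rename(
        columns={"mean": "accuracy_mean", "std": "accuracy_sd", "count": "n_seeds"}
    )
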