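"""Gait-cycle segmentation from the knee-flexion angle.

Heel strikes are located as the first local minimum of the knee-flexion
angle between consecutive maximum-flexion (swing) peaks; one gait cycle
runs from one heel strike to the next.  Trials can alternatively be cut
into a single fixed-duration window with no phase alignment, the
comparison condition for cycle segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import peak_prominences

from .synthetic import TrialRecording

DEFAULT_TARGET_FRAMES = 100
DEFAULT_MIN_PROMINENCE_DEG = 15.0
#: 0.4 of a nominal 1.4 Hz gait cycle.
DEFAULT_MIN_SEPARATION_S = 0.4 / 1.4


class TrialTooShortError(ValueError):
    """Trial shorter than the requested fixed window."""


@dataclass(frozen=True)
class GaitEventSet:
    """Detected knee-flexion peaks and the heel strikes between them."""

    knee_peak_indices: np.ndarray
    heel_strike_indices: np.ndarray
    source_trial: str

    def __post_init__(self) -> None:
        for name in ("knee_peak_indices", "heel_strike_indices"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, arr)


@dataclass
class Segment:
    """A fixed-length, multi-channel slice of one trial."""

    values: np.ndarray  # frames x channels
    channel_names: list[str]
    subject_id: str
    surface_name: str
    origin: tuple[str, int, int]  # (trial id, start sample, end sample)
    kind: str  # "cycle" | "window"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("segment values must be frames x channels")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match value columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("segment contains non-finite values")

    @property
    def frames(self) -> int:
        return self.values.shape[0]


class SegmentList(list):
    """List of segments that also reports how many cycles were rejected."""

    def __init__(self, segments: Sequence[Segment] = (), n_rejected: int = 0):
        super().__init__(segments)
        self.n_rejected = n_rejected


def _plateau_runs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compress equal-value runs; returns (run start indices, run values)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return np.empty(0, dtype=np.int64), values
    change = np.flatnonzero(np.diff(values) != 0) + 1
    starts = np.concatenate(([0], change))
    return starts, values[starts]


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Interior local maxima; a plateau maximum reports its first sample."""
    starts, vals = _plateau_runs(values)
    if len(vals) < 3:
        return np.empty(0, dtype=np.int64)
    interior = (vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])
    return starts[1:-1][interior]


def _local_minima(values: np.ndarray) -> np.ndarray:
    return _local_maxima(-np.asarray(values, dtype=np.float64))


def detect_knee_peaks(
    angle_series: np.ndarray,
    sample_rate_hz: float,
    min_prominence_deg: float = DEFAULT_MIN_PROMINENCE_DEG,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> np.ndarray:
    """Indices of maximum knee-flexion peaks.

    Local maxima are kept if their topographic prominence reaches
    ``min_prominence_deg``; remaining peaks closer than the minimum
    separation are thinned highest-first (earliest index wins a tie).
    A constant or too-short series yields an empty result.
    """
    angle = np.asarray(angle_series, dtype=np.float64)
    if angle.ndim != 1:
        raise ValueError("angle_series must be 1-D")
    candidates = _local_maxima(angle)
    if candidates.size == 0:
        return candidates
    prominences = peak_prominences(angle, candidates)[0]
    candidates = candidates[prominences >= min_prominence_deg]
    if candidates.size == 0:
        return candidates

    min_gap = min_separation_s * sample_rate_hz
    # Highest peak first; ties broken by earliest index.
    order = np.lexsort((candidates, -angle[candidates]))
    kept: list[int] = []
    for idx in candidates[order]:
        if all(abs(int(idx) - k) >= min_gap for k in kept):
            kept.append(int(idx))
    return np.asarray(sorted(kept), dtype=np.int64)


def detect_heel_strikes(
    angle_series: np.ndarray, peaks: Sequence[int]
) -> np.ndarray:
    """First local minimum of the angle between each consecutive peak pair.

    Plateau minima resolve to their first sample; a peak interval with no
    interior local minimum contributes nothing.  Fewer than two peaks
    yield an empty result.
    """
    angle = np.asarray(angle_series, dtype=np.float64)
    peaks = np.asarray(peaks, dtype=np.int64)
    if peaks.size and np.any(np.diff(peaks) <= 0):
        raise ValueError("peaks must be sorted ascending")
    strikes: list[int] = []
    for left, right in zip(peaks[:-1], peaks[1:]):
        minima = _local_minima(angle[left : right + 1]) + left
        minima = minima[(minima > left) & (minima < right)]
        if minima.size:
            strikes.append(int(minima[0]))
    return np.asarray(strikes, dtype=np.int64)


def detect_events(
    trial: TrialRecording,
    knee: str = "right",
    min_prominence_deg: float = DEFAULT_MIN_PROMINENCE_DEG,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
) -> GaitEventSet:
    """Run peak and heel-strike detection on a trial's knee channel."""
    channel = f"{knee}_knee_flexion"
    if channel not in trial.channels:
        raise ValueError(f"trial {trial.trial_id} has no channel {channel!r}")
    angle = trial.channels[channel]
    peaks = detect_knee_peaks(
        angle, trial.sample_rate_hz, min_prominence_deg, min_separation_s
    )
    return GaitEventSet(
        knee_peak_indices=peaks,
        heel_strike_indices=detect_heel_strikes(angle, peaks),
        source_trial=trial.trial_id,
    )


def _resample(series: np.ndarray, start: int, end: int, frames: int) -> np.ndarray:
    """Linearly resample series[start:end] to ``frames`` points."""
    xp = np.arange(start, end, dtype=np.float64)
    x = np.linspace(start, end - 1, frames)
    return np.interp(x, xp, np.asarray(series[start:end], dtype=np.float64))


def segment_cycles(
    trial: TrialRecording,
    events: GaitEventSet,
    target_frames: int = DEFAULT_TARGET_FRAMES,
    selected_channels: Sequence[str] | None = None,
    duration_filter: tuple[float, float] = (0.5, 2.0),
) -> SegmentList:
    """One segment per consecutive heel-strike pair, time-normalized.

    Each cycle [h_i, h_{i+1}) is linearly resampled to ``target_frames``
    frames per channel.  Cycles whose raw duration falls outside
    ``duration_filter`` times the trial's median cycle duration are
    rejected; the returned list reports the rejection count.
    """
    strikes = np.asarray(events.heel_strike_indices, dtype=np.int64)
    if strikes.size < 2:
        return SegmentList([], 0)
    names = list(selected_channels) if selected_channels else trial.channel_names
    missing = [c for c in names if c not in trial.channels]
    if missing:
        raise ValueError(f"unknown channel(s) {missing} in trial {trial.trial_id}")

    durations = np.diff(strikes)
    median = float(np.median(durations))
    lo, hi = duration_filter
    keep = (durations >= lo * median) & (durations <= hi * median)

    segments = []
    for i in np.flatnonzero(keep):
        start, end = int(strikes[i]), int(strikes[i + 1])
        values = np.column_stack(
            [_resample(trial.channels[c], start, end, target_frames) for c in names]
        )
        segments.append(
            Segment(
                values=values,
                channel_names=names,
                subject_id=trial.subject_id,
                surface_name=trial.surface_name,
                origin=(trial.trial_id, start, end),
                kind="cycle",
            )
        )
    return SegmentList(segments, n_rejected=int((~keep).sum()))


@dataclass(frozen=True)
class TrimPolicy:
    """Fraction of samples discarded at each end before windowing."""

    head_frac: float = 0.125
    tail_frac: float = 0.125

    def __post_init__(self) -> None:
        if not (0 <= self.head_frac < 0.5 and 0 <= self.tail_frac < 0.5):
            raise ValueError("trim fractions must lie in [0, 0.5)")


def segment_fixed_window(
    trial: TrialRecording,
    window_s: float = 4.0,
    trim_policy: TrimPolicy = TrimPolicy(),
    selected_channels: Sequence[str] | None = None,
) -> Segment:
    """A single fixed-duration window from the middle of the trial.

    The head/tail trim removes the acceleration and deceleration phases;
    the window is then centered in what remains.  No phase alignment is
    performed, so windows from different trials start at arbitrary points
    of the gait cycle.
    """
    n = trial.n_samples
    frames = int(round(window_s * trial.sample_rate_hz))
    lo = int(round(n * trim_policy.head_frac))
    hi = n - int(round(n * trim_policy.tail_frac))
    if hi - lo < frames:
        raise TrialTooShortError(
            f"trial {trial.trial_id!r}: {hi - lo} samples after trimming, "
            f"need {frames} for a {window_s} s window"
        )
    start = lo + (hi - lo - frames) // 2
    names = list(selected_channels) if selected_channels else trial.channel_names
    missing = [c for c in names if c not in trial.channels]
    if missing:
        raise ValueError(f"unknown channel(s) {missing} in trial {trial.trial_id}")
    values = np.column_stack(
        [np.asarray(trial.channels[c][start : start + frames], dtype=np.float64)
         for c in names]
    )
    return Segment(
        values=values,
        channel_names=names,
        subject_id=trial.subject_id,
        surface_name=trial.surface_name,
        origin=(trial.trial_id, start, start + frames),
        kind="window",
    )


def segment_trials(
    trials: Sequence[TrialRecording],
    mode: str = "cycles",
    target_frames: int = DEFAULT_TARGET_FRAMES,
    window_s: float = 4.0,
    trim_policy: TrimPolicy = TrimPolicy(),
    knee: str = "right",
    min_prominence_deg: float = DEFAULT_MIN_PROMINENCE_DEG,
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S,
    selected_channels: Sequence[str] | None = None,
) -> tuple[SegmentList, dict]:
    """Segment a whole dataset, skipping dropped trials.

    Returns the segments plus a bookkeeping report (trials in/used/dropped,
    cycles kept/rejected) so eliminated data stays auditable.
    """
    if mode not in ("cycles", "window"):
        raise ValueError(f"unknown segmentation mode {mode!r}")
    segments = SegmentList()
    report = {
        "mode": mode,
        "trials_in": len(trials),
        "trials_dropped": 0,
        "trials_too_short": 0,
        "cycles_kept": 0,
        "cycles_rejected": 0,
    }
    for trial in trials:
        if trial.dropped_flag:
            report["trials_dropped"] += 1
            continue
        if mode == "cycles":
            events = detect_events(
                trial, knee, min_prominence_deg, min_separation_s
            )
            segs = segment_cycles(
                trial, events, target_frames, selected_channels
            )
            segments.extend(segs)
            report["cycles_kept"] += len(segs)
            report["cycles_rejected"] += segs.n_rejected
        else:
            try:
                segments.append(
                    segment_fixed_window(
                        trial, window_s, trim_policy, selected_channels
                    )
                )
            except TrialTooShortError:
                report["trials_too_short"] += 1
    segments.n_rejected = report["cycles_rejected"]
    return segments, report
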