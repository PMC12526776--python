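"""Channel selection, amplitude normalization and tensor assembly.

The classifier consumes a dense tensor shaped
(#segments x #frames x #channels) with aligned per-segment surface and
subject labels.  Channels are chosen through the named sensor
combinations; amplitude normalization divides every channel by its
maximum absolute value (per trial by default, per segment at assembly),
bounding each channel to [-1, 1] while preserving sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .layout import SensorCombination
from .segmentation import Segment, SegmentList
from .synthetic import TrialRecording

#: Fixed project-wide class encoding.
SURFACE_CODES = {"grass": 0, "asphalt": 1}
SURFACE_FROM_CODE = {v: k for k, v in SURFACE_CODES.items()}


class AllZeroChannelWarning(UserWarning):
    """An all-zero channel cannot be amplitude-normalized."""


@dataclass
class SegmentTensor:
    """Model-ready stack of segments with aligned labels.

    values has shape (#segments, #frames, #channels); labels holds the
    surface code of each segment (grass=0, asphalt=1) and subjects the
    originating subject id.
    """

    values: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    channel_names: list[str]
    normalized_flag: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subjects = np.asarray(self.subjects)
        if self.values.ndim != 3:
            raise ValueError("values must be (#segments, #frames, #channels)")
        n = self.values.shape[0]
        if len(self.labels) != n or len(self.subjects) != n:
            raise ValueError("labels/subjects must align with values")
        if self.values.shape[2] != len(self.channel_names):
            raise ValueError("channel_names must match the channel axis")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def frames(self) -> int:
        return self.values.shape[1]

    def surface_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.labels == code))
            for name, code in SURFACE_CODES.items()
        }

    def subset(self, indices: np.ndarray) -> "SegmentTensor":
        return SegmentTensor(
            values=self.values[indices],
            labels=self.labels[indices],
            subjects=self.subjects[indices],
            channel_names=list(self.channel_names),
            normalized_flag=self.normalized_flag,
        )


def _check_channels(available: Sequence[str], wanted: Sequence[str]) -> None:
    missing = [c for c in wanted if c not in available]
    if missing:
        raise ValueError(f"missing channel(s): {missing}")


def select_channels(
    segments: Sequence[Segment] | SegmentTensor | TrialRecording,
    combination: SensorCombination,
):
    """Restrict data to a named sensor combination's channels.

    Works on a list of segments, an assembled tensor, or a raw trial; the
    result keeps the canonical channel order (layout order x axis x,y,z)
    and has 3 channels per sensor in the combination.
    """
    wanted = combination.channel_names
    if isinstance(segments, SegmentTensor):
        _check_channels(segments.channel_names, wanted)
        cols = [segments.channel_names.index(c) for c in wanted]
        return SegmentTensor(
            values=segments.values[:, :, cols],
            labels=segments.labels,
            subjects=segments.subjects,
            channel_names=wanted,
            normalized_flag=segments.normalized_flag,
        )
    if isinstance(segments, TrialRecording):
        _check_channels(segments.channel_names, wanted)
        return TrialRecording(
            trial_id=segments.trial_id,
            subject_id=segments.subject_id,
            surface_name=segments.surface_name,
            sample_rate_hz=segments.sample_rate_hz,
            channels={c: segments.channels[c] for c in wanted},
            true_heel_strikes=segments.true_heel_strikes.copy(),
            dropped_flag=segments.dropped_flag,
        )
    out = SegmentList(
        n_rejected=getattr(segments, "n_rejected", 0)
    )
    for seg in segments:
        _check_channels(seg.channel_names, wanted)
        cols = [seg.channel_names.index(c) for c in wanted]
        out.append(
            Segment(
                values=seg.values[:, cols],
                channel_names=wanted,
                subject_id=seg.subject_id,
                surface_name=seg.surface_name,
                origin=seg.origin,
                kind=seg.kind,
            )
        )
    return out


def _normalize_columns(values: np.ndarray, context: str) -> np.ndarray:
    """Divide each column by its maximum absolute value."""
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite values in {context}")
    scale = np.max(np.abs(values), axis=0)
    zero = scale == 0
    if np.any(zero):
        warnings.warn(
            f"all-zero channel(s) left unchanged in {context}",
            AllZeroChannelWarning,
            stacklevel=3,
        )
        scale = np.where(zero, 1.0, scale)
    return values / scale


def normalize_amplitude(data, exclude_channels: Sequence[str] = ()):
    """Amplitude-normalize a trial, a segment, or a whole tensor.

    Every channel is divided by its maximum *absolute* value over the
    trial (or segment), so the output is bounded to [-1, 1] with sign
    preserved; all-zero channels are returned unchanged with a warning.
    The operation is idempotent.  ``exclude_channels`` (trials only)
    leaves named channels untouched — the pipeline uses it to keep the
    knee-flexion angle in native degrees for event detection.
    """
    if isinstance(data, TrialRecording):
        stacked = np.column_stack(
            [np.asarray(v, dtype=np.float64) for v in data.channels.values()]
        )
        normed = _normalize_columns(stacked, f"trial {data.trial_id}")
        return TrialRecording(
            trial_id=data.trial_id,
            subject_id=data.subject_id,
            surface_name=data.surface_name,
            sample_rate_hz=data.sample_rate_hz,
            channels={
                name: (
                    np.asarray(data.channels[name], dtype=np.float64)
                    if name in exclude_channels
                    else normed[:, i]
                )
                for i, name in enumerate(data.channels)
            },
            true_heel_strikes=data.true_heel_strikes.copy(),
            dropped_flag=data.dropped_flag,
        )
    if isinstance(data, Segment):
        return Segment(
            values=_normalize_columns(
                np.asarray(data.values, dtype=np.float64),
                f"segment of {data.origin[0]}",
            ),
            channel_names=list(data.channel_names),
            subject_id=data.subject_id,
            surface_name=data.surface_name,
            origin=data.origin,
            kind=data.kind,
        )
    if isinstance(data, SegmentTensor):
        values = np.asarray(data.values, dtype=np.float64)
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite values in tensor")
        scale = np.max(np.abs(values), axis=1, keepdims=True)
        zero = scale == 0
        if np.any(zero):
            warnings.warn(
                "all-zero channel(s) left unchanged in tensor",
                AllZeroChannelWarning,
                stacklevel=2,
            )
            scale = np.where(zero, 1.0, scale)
        return SegmentTensor(
            values=values / scale,
            labels=data.labels,
            subjects=data.subjects,
            channel_names=list(data.channel_names),
            normalized_flag=True,
        )
    raise TypeError(f"cannot normalize {type(data).__name__}")


def assemble_tensor(
    segments: Sequence[Segment], normalize: bool = False
) -> SegmentTensor:
    """Stack segments (input order) into a SegmentTensor.

    With ``normalize`` on, each (segment, channel) is divided by its
    maximum absolute value after stacking.  All segments must share frame
    count and channel set; offenders are reported by position.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments to assemble")
    ref_shape = segments[0].values.shape
    ref_channels = segments[0].channel_names
    bad = [
        i
        for i, s in enumerate(segments)
        if s.values.shape != ref_shape or s.channel_names != ref_channels
    ]
    if bad:
        raise ValueError(
            f"segments at positions {bad} do not match shape {ref_shape} "
            f"/ channel set of segment 0"
        )
    unknown = [s.surface_name for s in segments if s.surface_name not in SURFACE_CODES]
    if unknown:
        raise ValueError(f"unknown surface label(s): {sorted(set(unknown))}")
    tensor = SegmentTensor(
        values=np.stack([s.values for s in segments]),
        labels=np.array([SURFACE_CODES[s.surface_name] for s in segments]),
        subjects=np.array([s.subject_id for s in segments]),
        channel_names=list(ref_channels),
    )
    if normalize:
        tensor = normalize_amplitude(tensor)
    return tensor
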