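"""Synthetic running trials with known ground truth.

The real study data (40 runners, 80 overground runs per surface on grass and
asphalt, full-body inertial suit) are not publicly available, so this module
generates trials with the statistical structure the downstream analysis
assumes:

* periodic gait waveforms built from Gaussian bumps over cycle phase,
* subject-specific signatures (amplitude and cadence perturbations drawn
  once per subject and reused in every trial),
* surface effects that are strongest at the feet and fade up the body
  chain — a multiplicative gain on the impact transient and a brief
  high-frequency burst after each heel strike,
* a knee-flexion angle channel whose first local minimum after each
  maximum-flexion (swing) peak falls exactly on the ground-truth heel
  strike, which is what the segmentation stage exploits.

Every trial carries its ground-truth heel-strike sample indices, so
segmentation, splitting and classification can all be validated against
known answers.  Cycle boundaries are snapped to the sample grid so ground
truth is exact at the configured sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .layout import (
    AXES,
    KNEE_CHANNELS,
    PROXIMITY_WEIGHT,
    SensorLayout,
    channel_name,
)

SURFACE_NAMES = ("grass", "asphalt")

# Region-scale amplitudes (m/s^2 for acceleration, rad/s for angular
# velocity).  Feet move hardest; the head barely at all.
_ACCEL_SCALE = {
    "head": 3.0,
    "shoulder": 4.0,
    "upper_arm": 5.0,
    "hand": 6.0,
    "pelvis": 8.0,
    "lower_leg": 20.0,
    "foot": 30.0,
}
_GYRO_SCALE = {
    "head": 1.0,
    "shoulder": 1.5,
    "upper_arm": 1.8,
    "hand": 2.0,
    "pelvis": 2.5,
    "lower_leg": 6.0,
    "foot": 8.0,
}
#: Angular-velocity channels see surface effects at a fraction of the
#: acceleration proximity weight, making acceleration the more informative
#: signal by construction.
GYRO_PROXIMITY_FACTOR = 0.4

#: Phase of the maximum knee-flexion (swing) peak within a gait cycle.
KNEE_SWING_PHASE = 0.80
#: Phase of the impact transient just after heel strike.
IMPACT_PHASE = 0.03


class SurfaceError(ValueError):
    """Raised for an unknown or invalid surface specification."""


@dataclass(frozen=True)
class SurfaceParams:
    """Surface-dependent generator settings.

    impact_gain multiplies the amplitude of the designated impact component
    of each channel (scaled by the channel's proximity weight); hf_noise_sd
    is the standard deviation (m/s^2, at proximity weight 1) of the brief
    high-frequency burst injected after each heel strike; cycle_cv is the
    coefficient of variation of cycle duration.
    """

    surface_name: str
    impact_gain: float = 1.0
    hf_noise_sd: float = 0.0
    cycle_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.surface_name not in SURFACE_NAMES:
            raise SurfaceError(
                f"unknown surface {self.surface_name!r}; "
                f"expected one of {SURFACE_NAMES}"
            )
        if self.impact_gain <= 0:
            raise ValueError("impact_gain must be > 0")
        if self.hf_noise_sd < 0:
            raise ValueError("hf_noise_sd must be >= 0")
        if not 0 <= self.cycle_cv < 0.5:
            raise ValueError("cycle_cv must be in [0, 0.5)")


#: Default surfaces: asphalt is the harder surface — stronger impact
#: transient, more post-impact vibration, slightly steadier cycles.  The
#: contrasts are deliberately subtle (the two surfaces produce "very
#: similar" signals) and partly confounded with the subject signature,
#: so between-subject generalization is genuinely harder than
#: within-subject classification.
DEFAULT_SURFACES = (
    SurfaceParams("grass", impact_gain=1.0, hf_noise_sd=0.25, cycle_cv=0.05),
    SurfaceParams("asphalt", impact_gain=1.35, hf_noise_sd=0.5, cycle_cv=0.04),
)


def null_surfaces() -> tuple[SurfaceParams, SurfaceParams]:
    """Surfaces with every discriminating effect zeroed.

    Under these parameters grass and asphalt trials are draws from the same
    distribution, so any classifier's expected test accuracy is 50%.
    """
    return (
        SurfaceParams("grass", impact_gain=1.0, hf_noise_sd=0.0, cycle_cv=0.05),
        SurfaceParams("asphalt", impact_gain=1.0, hf_noise_sd=0.0, cycle_cv=0.05),
    )


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian bump over cycle phase: a * exp(-(phi-mu)^2 / 2 sigma^2)."""

    amplitude: float
    center: float
    width: float
    impact: bool = False

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if not 0 <= self.center < 1:
            raise ValueError("center must lie in [0, 1)")


@dataclass(frozen=True)
class ChannelTemplate:
    """Population-mean waveform of one channel over a gait cycle."""

    baseline: float
    components: tuple[GaussianComponent, ...]
    proximity_weight: float

    def __post_init__(self) -> None:
        if not 0 <= self.proximity_weight <= 1:
            raise ValueError("proximity_weight must lie in [0, 1]")


def _region(sensor: str) -> str:
    for key in ("foot", "lower_leg", "upper_arm", "shoulder", "hand"):
        if key in sensor:
            return key
    return sensor  # head, pelvis


def _sensor_components(
    scale: float, axis_idx: int, left_side: bool, impact_frac: float
) -> tuple[GaussianComponent, ...]:
    """Deterministic bump set for one sensor channel.

    Left-side sensors run half a cycle out of phase with the right side
    (contralateral limbs).  Axis index nudges bump centers so the three
    axes of one sensor are correlated but not identical.
    """
    shift = 0.5 if left_side else 0.0

    def mu(base: float) -> float:
        return (base + 0.04 * axis_idx + shift) % 1.0

    return (
        GaussianComponent(impact_frac * scale, mu(IMPACT_PHASE), 0.015, impact=True),
        GaussianComponent(0.80 * scale, mu(0.12), 0.06),
        GaussianComponent(-0.35 * scale, mu(0.38), 0.08),
        GaussianComponent(0.45 * scale, mu(0.60), 0.10),
    )


def default_templates(layout: SensorLayout | None = None) -> dict[str, ChannelTemplate]:
    """Fixed per-channel templates for the full sensor layout plus knees."""
    layout = layout or SensorLayout()
    templates: dict[str, ChannelTemplate] = {}
    for sensor in layout.sensors:
        region = _region(sensor)
        left = sensor.startswith("left")
        w_acc = PROXIMITY_WEIGHT[sensor]
        w_gyr = min(1.0, GYRO_PROXIMITY_FACTOR * w_acc)
        for axis_idx, axis in enumerate(AXES):
            templates[channel_name(sensor, "acceleration", axis)] = ChannelTemplate(
                baseline=9.81 if axis == "z" else 0.0,
                components=_sensor_components(
                    _ACCEL_SCALE[region], axis_idx, left, impact_frac=0.55
                ),
                proximity_weight=w_acc,
            )
            templates[channel_name(sensor, "angular_velocity", axis)] = ChannelTemplate(
                baseline=0.0,
                components=_sensor_components(
                    _GYRO_SCALE[region], axis_idx, left, impact_frac=0.40
                ),
                proximity_weight=w_gyr,
            )
    for knee in KNEE_CHANNELS:
        shift = 0.5 if knee.startswith("left") else 0.0

        def kmu(base: float) -> float:
            return (base + shift) % 1.0

        # Swing-phase flexion maximum, a small stance-phase bump, and a
        # sharp dip whose minimum marks heel strike at phase 0.  Surface
        # effects do not act on joint kinematics here (weight 0), which
        # keeps event detection well-posed on both surfaces.
        templates[knee] = ChannelTemplate(
            baseline=18.0,
            components=(
                GaussianComponent(38.0, kmu(KNEE_SWING_PHASE), 0.07),
                GaussianComponent(8.0, kmu(0.25), 0.10),
                GaussianComponent(-10.0, kmu(0.0), 0.03),
            ),
            proximity_weight=0.0,
        )
    return templates


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and noise settings for the synthetic cohort.

    Defaults mirror the study: 40 runners, 80 trials per surface each,
    runs between cones 20 m apart at a comfortable pace, 12 triaxial
    sensors recorded at 100 Hz, occasional trials dropped because a sensor
    fell off.
    """

    n_subjects: int = 40
    trials_per_surface: int = 80
    sample_rate_hz: float = 100.0
    run_distance_m: float = 20.0
    duration_s: float | None = None  # None: derived as distance / speed
    cadence_mean_hz: float = 1.4
    cadence_sd_hz: float = 0.07
    cadence_clip_hz: tuple[float, float] = (1.25, 1.55)
    speed_mean_mps: float = 3.5
    speed_sd_mps: float = 0.15
    speed_clip_mps: tuple[float, float] = (3.2, 3.7)
    signature_scale: float = 0.25
    #: correlation of one subject's signature draws across channels; the
    #: shared part is a body-wide "gait style" (e.g. impact hardness)
    #: that no amount of channel averaging removes.
    signature_channel_corr: float = 0.7
    drop_rate: float = 0.01
    noise_accel_sd: float = 0.3
    noise_gyro_sd: float = 0.1
    noise_knee_sd: float = 0.3
    hf_burst_s: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.trials_per_surface < 1:
            raise ValueError("trials_per_surface must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if not 0 <= self.drop_rate < 1:
            raise ValueError("drop_rate must lie in [0, 1)")
        if self.signature_scale < 0:
            raise ValueError("signature_scale must be >= 0")


@dataclass(frozen=True)
class SubjectProfile:
    """One runner: gait tempo, speed and a fixed personal signature.

    signature_draws holds one standard-normal draw per (channel, waveform
    component); the draw is made once when the profile is created and is
    reused verbatim in every trial, so a subject looks like themselves
    across their whole recording session.
    """

    subject_id: str
    cadence_hz: float
    speed_mps: float
    signature_scale: float
    signature_draws: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.cadence_hz <= 0:
            raise ValueError("cadence_hz must be > 0")
        if self.speed_mps <= 0:
            raise ValueError("speed_mps must be > 0")
        if self.signature_scale < 0:
            raise ValueError("signature_scale must be >= 0")


@dataclass
class TrialRecording:
    """One run: multi-channel time series plus labels and ground truth."""

    trial_id: str
    subject_id: str
    surface_name: str
    sample_rate_hz: float
    channels: dict[str, np.ndarray]
    true_heel_strikes: np.ndarray
    dropped_flag: bool = False

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channel series must have equal length")
        n = lengths.pop()
        if n < 2:
            raise ValueError("channel series must have length >= 2")
        hs = np.asarray(self.true_heel_strikes, dtype=np.int64)
        if hs.size and (np.any(np.diff(hs) <= 0) or hs[0] < 0 or hs[-1] >= n):
            raise ValueError("true_heel_strikes must be strictly increasing "
                             "and within series bounds")
        self.true_heel_strikes = hs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Hierarchical stream: same (seed, key) always yields the same draws."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def make_population(
    n_subjects: int,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    templates: Mapping[str, ChannelTemplate] | None = None,
) -> list[SubjectProfile]:
    """Draw a cohort of runner profiles.

    Deterministic for a fixed seed; each subject's signature draws come
    from their own sub-stream, so enlarging the cohort does not perturb
    earlier subjects.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or GeneratorConfig()
    templates = templates or default_templates()
    profiles = []
    for i in range(n_subjects):
        rng = _rng(seed, 1, i)
        cadence = _truncated_normal(
            rng, config.cadence_mean_hz, config.cadence_sd_hz, *config.cadence_clip_hz
        )
        speed = _truncated_normal(
            rng, config.speed_mean_mps, config.speed_sd_mps, *config.speed_clip_mps
        )
        # Per-channel, per-component draws with a shared body-wide part:
        # z_ck = rho * u_k + sqrt(1 - rho^2) * v_ck, all fixed for life.
        rho = config.signature_channel_corr
        max_k = max(len(t.components) for t in templates.values())
        shared = rng.normal(0.0, 1.0, size=max_k)
        draws = {
            name: np.clip(
                rho * shared[: len(tpl.components)]
                + np.sqrt(1.0 - rho**2)
                * rng.normal(0.0, 1.0, size=len(tpl.components)),
                -2.0,
                2.0,
            )
            for name, tpl in templates.items()
        }
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                cadence_hz=cadence,
                speed_mps=speed,
                signature_scale=config.signature_scale,
                signature_draws=draws,
            )
        )
    return profiles


def _circular_gaussian(phase: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    d = np.mod(phase - mu + 0.5, 1.0) - 0.5
    return np.exp(-0.5 * (d / sigma) ** 2)


def _cycle_layout(
    n_samples: int,
    cadence_hz: float,
    cycle_cv: float,
    fs: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Plan cycle boundaries on the sample grid.

    Returns (boundaries, durations, phase, last_recoverable): integer
    heel-strike samples b_0..b_L, the planned duration (samples) of the
    cycle starting at each boundary, the per-sample cycle phase in
    [0, 1), and whether the last boundary is recoverable by event
    detection.  The series starts mid-cycle (the runner is already
    moving) and ends inside a partial cycle, so phase is defined for
    every sample.

    The trailing partial cycle is shaped so its status is unambiguous:
    if the tail is long enough (>= 0.45 of a cycle) its duration is
    rescaled so the swing peak falls well inside the series — the last
    boundary then has a following flexion maximum and is detectable;
    otherwise the tail never reaches the swing phase and the last
    boundary is deliberately left out of the ground truth.
    """
    mean_d = fs / cadence_hz

    def draw_duration() -> int:
        jitter = 1.0 + cycle_cv * float(np.clip(rng.normal(), -2.0, 2.0))
        return max(4, int(round(mean_d * jitter)))

    d_lead = draw_duration()
    b0 = max(1, int(round(rng.uniform(0.30, 0.45) * d_lead)))
    boundaries = [b0]
    durations: list[float] = []
    while True:
        d = draw_duration()
        nxt = boundaries[-1] + d
        if nxt > n_samples - 1:
            durations.append(float(d))  # trailing partial cycle
            break
        durations.append(float(d))
        boundaries.append(nxt)

    bounds = np.asarray(boundaries, dtype=np.int64)
    tail = n_samples - 1 - bounds[-1]
    last_recoverable = tail >= 0.45 * durations[-1]
    if last_recoverable:
        # Swing peak at 0.8 of the (rescaled) trailing cycle: comfortably
        # inside the series, next heel-strike dip outside it.
        durations[-1] = max(tail / 0.93, 4.0)
    durs = np.asarray(durations, dtype=np.float64)

    t = np.arange(n_samples, dtype=np.float64)
    phase = np.empty(n_samples, dtype=np.float64)
    phase[:b0] = 1.0 - (b0 - t[:b0]) / d_lead
    np.clip(phase[:b0], 0.0, None, out=phase[:b0])
    for j, b in enumerate(bounds):
        end = bounds[j + 1] if j + 1 < len(bounds) else n_samples
        phase[b:end] = (t[b:end] - b) / durs[j]
    return bounds, durs, phase, bool(last_recoverable)


def simulate_trial(
    subject: SubjectProfile,
    surface: SurfaceParams,
    layout: SensorLayout | None = None,
    duration_s: float | None = None,
    rng: np.random.Generator | None = None,
    config: GeneratorConfig | None = None,
    templates: Mapping[str, ChannelTemplate] | None = None,
    trial_id: str = "trial",
) -> TrialRecording:
    """Synthesize one run of a subject over a surface.

    Each channel is baseline + sum of subject- and surface-modulated
    Gaussian bumps over cycle phase, plus sensor noise; asphalt-style
    surfaces add a high-frequency burst for ``hf_burst_s`` seconds after
    every heel strike, scaled by the channel's proximity weight.
    """
    if not isinstance(surface, SurfaceParams):
        raise SurfaceError(f"expected SurfaceParams, got {type(surface).__name__}")
    config = config or GeneratorConfig()
    layout = layout or SensorLayout()
    templates = templates or default_templates(layout)
    rng = rng if rng is not None else np.random.default_rng(0)

    fs = config.sample_rate_hz
    if duration_s is None:
        duration_s = config.duration_s
    if duration_s is None:
        duration_s = config.run_distance_m / subject.speed_mps
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = int(round(duration_s * fs))
    if n < 8:
        raise ValueError("trial too short to contain a gait cycle")

    bounds, durs, phase, last_recoverable = _cycle_layout(
        n, subject.cadence_hz, surface.cycle_cv, fs, rng
    )

    # Ground truth keeps only recoverable heel strikes: every boundary
    # followed by a full cycle, plus the last one when the trailing
    # partial cycle covers the swing peak (so a flexion maximum follows
    # it and the first-minimum rule can find the strike).
    truth = bounds if last_recoverable else bounds[:-1]

    s = subject.signature_scale
    gain = surface.impact_gain

    # High-frequency post-impact burst mask (shared across channels).
    burst_len = max(1, int(round(config.hf_burst_s * fs)))
    burst_mask = np.zeros(n, dtype=bool)
    for b in bounds:
        burst_mask[b : min(n, b + burst_len)] = True
    n_burst = int(burst_mask.sum())

    channels: dict[str, np.ndarray] = {}
    for name, tpl in templates.items():
        z = subject.signature_draws.get(name)
        w = tpl.proximity_weight
        y = np.full(n, tpl.baseline, dtype=np.float64)
        for k, comp in enumerate(tpl.components):
            a = comp.amplitude
            if z is not None and s > 0:
                a *= 1.0 + s * float(z[k])
            if comp.impact:
                a *= 1.0 + w * (gain - 1.0)
            y += a * _circular_gaussian(phase, comp.center, comp.width)

        if name in KNEE_CHANNELS:
            if config.noise_knee_sd > 0:
                # Kinematic output is smooth: band-limit the noise so it
                # cannot flip the sign of the steep pre-impact slope and
                # spawn spurious local minima.
                white = rng.normal(0.0, config.noise_knee_sd, size=n)
                b_f, a_f = butter(2, 8.0 / (fs / 2.0))
                y += filtfilt(b_f, a_f, white)
        else:
            sd = (
                config.noise_accel_sd
                if "_acceleration_" in name
                else config.noise_gyro_sd
            )
            if sd > 0:
                y += rng.normal(0.0, sd, size=n)
            if surface.hf_noise_sd > 0 and w > 0 and n_burst:
                # The post-impact vibration also depends on the subject's
                # impact style (their shared impact-component draw), so the
                # burst is not a pure surface fingerprint.
                style = 1.0
                if z is not None and s > 0:
                    impact_k = next(
                        (k for k, comp in enumerate(tpl.components) if comp.impact),
                        None,
                    )
                    if impact_k is not None:
                        style = max(0.2, 1.0 + s * float(z[impact_k]))
                y[burst_mask] += rng.normal(
                    0.0, surface.hf_noise_sd * w * style, size=n_burst
                )
        channels[name] = y

    return TrialRecording(
        trial_id=trial_id,
        subject_id=subject.subject_id,
        surface_name=surface.surface_name,
        sample_rate_hz=fs,
        channels=channels,
        true_heel_strikes=truth,
        dropped_flag=False,
    )


def simulate_dataset(
    population: Sequence[SubjectProfile],
    surfaces: Sequence[SurfaceParams] = DEFAULT_SURFACES,
    trials_per_surface: int = 80,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    templates: Mapping[str, ChannelTemplate] | None = None,
) -> list[TrialRecording]:
    """Simulate the full cohort: every subject runs every surface repeatedly.

    Trials whose sensor "fell off" (Bernoulli with the configured drop
    rate) are flagged, not deleted, so the elimination bookkeeping stays
    auditable downstream.
    """
    if not population:
        raise ValueError("population must not be empty")
    if trials_per_surface < 1:
        raise ValueError("trials_per_surface must be >= 1")
    config = config or GeneratorConfig()
    templates = templates or default_templates()
    trials: list[TrialRecording] = []
    for i, subject in enumerate(population):
        for j, surface in enumerate(surfaces):
            for t in range(trials_per_surface):
                rng = _rng(seed, 2, i, j, t)
                trial = simulate_trial(
                    subject,
                    surface,
                    duration_s=config.duration_s,
                    rng=rng,
                    config=config,
                    templates=templates,
                    trial_id=f"{subject.subject_id}_{surface.surface_name}_{t:03d}",
                )
                if config.drop_rate > 0:
                    trial.dropped_flag = bool(rng.random() < config.drop_rate)
                trials.append(trial)
    return trials
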