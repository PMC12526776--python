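"""Event detection and segmentation against brute-force oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from runsurf.segmentation import (
    GaitEventSet,
    TrialTooShortError,
    TrimPolicy,
    detect_events,
    detect_heel_strikes,
    detect_knee_peaks,
    segment_cycles,
    segment_fixed_window,
    segment_trials,
)
from runsurf.synthetic import (
    GeneratorConfig,
    SurfaceParams,
    make_population,
    simulate_trial,
)

NOISE_FREE = GeneratorConfig(
    noise_accel_sd=0.0, noise_gyro_sd=0.0, noise_knee_sd=0.0, drop_rate=0.0
)
QUIET = SurfaceParams("grass", impact_gain=1.0, hf_noise_sd=0.0, cycle_cv=0.0)


# -- independent brute-force oracle ---------------------------------------


def brute_local_maxima(v):
    """Every interior local maximum; plateaus report their first sample."""
    out = []
    n = len(v)
    i = 1
    while i < n - 1:
        if v[i] > v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return out


def brute_prominence(v, peak):
    """Height above the higher of the two valley floors, walking out to
    the nearest strictly-higher sample (or the series edge) on each side."""
    h = v[peak]
    left = peak
    while left > 0 and v[left - 1] <= h:
        left -= 1
    left_min = v[left:peak].min() if left < peak else h
    right = peak
    n = len(v)
    while right < n - 1 and v[right + 1] <= h:
        right += 1
    right_min = v[peak + 1 : right + 1].min() if right > peak else h
    return h - max(left_min, right_min)


def brute_detect_peaks(v, fs, min_prom, min_sep_s):
    cands = [p for p in brute_local_maxima(v) if brute_prominence(v, p) >= min_prom]
    # highest first, earliest on ties; enforce separation greedily
    cands.sort(key=lambda p: (-v[p], p))
    kept = []
    for p in cands:
        if all(abs(p - q) >= min_sep_s * fs for q in kept):
            kept.append(p)
    return sorted(kept)


def brute_first_min_between(v, left, right):
    for i in range(left + 1, right):
        if v[i] < v[i - 1]:
            j = i
            while j + 1 <= right and v[j + 1] == v[i]:
                j += 1
            if j < right and v[j + 1] > v[i]:
                return i
    return None


# -- worked examples -------------------------------------------------------


def test_sine_peaks_and_heel_strikes():
    n = np.arange(400)
    theta = 30 + 30 * np.sin(2 * np.pi * n / 100)
    peaks = detect_knee_peaks(theta, sample_rate_hz=100)
    np.testing.assert_array_equal(peaks, [25, 125, 225, 325])
    strikes = detect_heel_strikes(theta, [25, 125, 225])
    np.testing.assert_array_equal(strikes, [75, 175])


def test_first_minimum_wins_over_deepest():
    # two interior minima between the peaks: n=40 (value 5) first,
    # n=60 (value 3) deeper — the first one is the heel strike
    knots_x = [0, 20, 40, 50, 60, 80, 99]
    knots_y = [0, 10, 5, 8, 3, 10, 0]
    v = np.interp(np.arange(100), knots_x, knots_y)
    strikes = detect_heel_strikes(v, [20, 80])
    np.testing.assert_array_equal(strikes, [40])


def test_plateau_minimum_resolves_to_first_sample():
    v = np.array([0, 5, 3, 1, 1, 1, 2, 5, 0], dtype=float)
    strikes = detect_heel_strikes(v, [1, 7])
    np.testing.assert_array_equal(strikes, [3])


def test_constant_series_yields_nothing():
    assert len(detect_knee_peaks(np.full(50, 30.0), 100)) == 0
    assert len(detect_heel_strikes(np.full(50, 30.0), [])) == 0
    assert len(detect_heel_strikes(np.arange(50.0), [10])) == 0  # < 2 peaks


# -- oracle equivalence ----------------------------------------------------


def test_extremum_detection_matches_brute_force_scan(rng):
    for _ in range(60):
        n = int(rng.integers(10, 2000))
        v = rng.normal(0, 20, size=n).round(1)  # rounding creates plateaus
        prom = float(rng.uniform(0, 25))
        sep = float(rng.uniform(0, 0.3))
        got = detect_knee_peaks(v, 100.0, prom, sep)
        want = brute_detect_peaks(v, 100.0, prom, sep)
        np.testing.assert_array_equal(got, want)
        peaks = brute_detect_peaks(v, 100.0, 0.0, 0.0)
        got_hs = detect_heel_strikes(v, peaks)
        want_hs = [
            m
            for l, r in zip(peaks[:-1], peaks[1:])
            if (m := brute_first_min_between(v, l, r)) is not None
        ]
        np.testing.assert_array_equal(got_hs, want_hs)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    st.lists(st.integers(min_value=-50, max_value=50), min_size=3, max_size=200),
    st.floats(min_value=0, max_value=30),
)
def test_peak_detection_property(values, prom):
    v = np.asarray(values, dtype=float)
    got = detect_knee_peaks(v, 100.0, prom, 0.0)
    assert list(got) == brute_detect_peaks(v, 100.0, prom, 0.0)


# -- exact recovery on synthetic ground truth ------------------------------


def test_noise_free_recovery_is_exact():
    pop = make_population(3, NOISE_FREE, seed=21)
    for i, p in enumerate(pop):
        trial = simulate_trial(
            p, QUIET, rng=np.random.default_rng(100 + i), config=NOISE_FREE
        )
        events = detect_events(trial)
        np.testing.assert_array_equal(
            events.heel_strike_indices, trial.true_heel_strikes
        )
        # one swing peak per boundary, plus lead-in and trailing partials
        assert len(events.knee_peak_indices) == len(trial.true_heel_strikes) + 1


def test_default_noise_recovery_within_two_samples(desk_trials):
    total, close = 0, 0
    for trial in desk_trials[:40]:
        events = detect_events(trial)
        det = events.heel_strike_indices
        truth = trial.true_heel_strikes
        assert len(det) == len(truth)
        total += len(truth)
        close += int(np.sum(np.abs(det - truth) <= 2))
    assert close / total >= 0.99


# -- cycle segmentation ----------------------------------------------------


def _toy_trial(n=400, fs=100.0):
    from runsurf.synthetic import TrialRecording

    t = np.arange(n)
    return TrialRecording(
        trial_id="toy",
        subject_id="S000",
        surface_name="grass",
        sample_rate_hz=fs,
        channels={
            "right_knee_flexion": 30 + 30 * np.sin(2 * np.pi * t / 100),
            "right_foot_acceleration_z": np.cos(2 * np.pi * t / 100),
        },
        true_heel_strikes=np.array([75, 175, 275]),
    )


def test_cycle_count_is_strikes_minus_one():
    trial = _toy_trial()
    events = GaitEventSet(
        knee_peak_indices=np.array([25, 125, 225, 325]),
        heel_strike_indices=np.array([100, 200, 300]),
        source_trial="toy",
    )
    segs = segment_cycles(trial, events, target_frames=100)
    assert len(segs) == 2
    assert all(s.values.shape == (100, 2) for s in segs)
    assert segs.n_rejected == 0


def test_resampling_preserves_extrema():
    # a 120-sample cycle resampled to 100 frames keeps min/max within 1%
    # of the waveform range
    from runsurf.synthetic import TrialRecording

    t = np.arange(360)
    wave = np.sin(2 * np.pi * t / 120)
    trial = TrialRecording(
        trial_id="wave",
        subject_id="S000",
        surface_name="grass",
        sample_rate_hz=100.0,
        channels={"c": wave},
        true_heel_strikes=np.array([0, 120, 240]),
    )
    events = GaitEventSet(
        knee_peak_indices=np.array([0, 120, 240]),
        heel_strike_indices=np.array([0, 120, 240]),
        source_trial="wave",
    )
    segs = segment_cycles(trial, events, target_frames=100)
    rng_span = wave.max() - wave.min()
    for s in segs:
        assert abs(s.values.max() - wave.max()) <= 0.01 * rng_span
        assert abs(s.values.min() - wave.min()) <= 0.01 * rng_span


def test_duration_filter_reports_rejections():
    trial = _toy_trial(n=800)
    events = GaitEventSet(
        knee_peak_indices=np.array([10, 110, 210, 310, 420]),
        heel_strike_indices=np.array([100, 200, 300, 310, 700]),
        source_trial="toy",
    )
    segs = segment_cycles(trial, events, target_frames=50)
    # median duration 100; the 10-sample and 390-sample cycles fall
    # outside [0.5, 2.0] x median
    assert segs.n_rejected == 2
    assert len(segs) == 4 - 2


def test_label_propagation(desk_trials):
    trial = desk_trials[0]
    segs = segment_cycles(trial, detect_events(trial), target_frames=100)
    assert all(s.subject_id == trial.subject_id for s in segs)
    assert all(s.surface_name == trial.surface_name for s in segs)
    assert all(s.origin[0] == trial.trial_id for s in segs)


def test_unknown_channel_rejected(desk_trials):
    trial = desk_trials[0]
    with pytest.raises(ValueError, match="nope"):
        segment_cycles(
            trial, detect_events(trial), selected_channels=["nope"]
        )


# -- fixed windows ---------------------------------------------------------


def test_window_position_arithmetic():
    trial = _toy_trial(n=800)  # 8 s at 100 Hz
    seg = segment_fixed_window(trial, window_s=4.0, trim_policy=TrimPolicy(0.125, 0.125))
    # trim 100 samples each end -> [100, 700); centered 400 -> [200, 600)
    assert seg.origin == ("toy", 200, 600)
    assert seg.frames == 400
    assert seg.kind == "window"


def test_window_too_short_names_trial():
    trial = _toy_trial(n=300)  # 3 s
    with pytest.raises(TrialTooShortError, match="toy"):
        segment_fixed_window(trial, window_s=4.0)


def test_windows_are_phase_unaligned_but_cycles_align(desk_trials):
    """Two same-subject same-surface trials: their fixed windows start at
    arbitrary gait phases (low correlation), while their averaged cycle
    segments are near-identical."""
    trials = [
        t
        for t in desk_trials
        if t.subject_id == "S000" and t.surface_name == "grass"
        and not t.dropped_flag
    ][:2]
    w = [
        segment_fixed_window(t, selected_channels=["right_foot_acceleration_z"])
        for t in trials
    ]
    cyc = [
        np.mean(
            [
                s.values[:, 0]
                for s in segment_cycles(
                    t, detect_events(t), 100,
                    selected_channels=["right_foot_acceleration_z"],
                )
            ],
            axis=0,
        )
        for t in trials
    ]
    cycle_r = np.corrcoef(cyc[0], cyc[1])[0, 1]
    win_r = np.corrcoef(w[0].values[:, 0], w[1].values[:, 0])[0, 1]
    assert cycle_r > 0.95
    assert cycle_r > win_r


def test_segment_trials_bookkeeping(desk_trials):
    segments, report = segment_trials(desk_trials)
    assert report["trials_in"] == len(desk_trials)
    assert report["trials_dropped"] == sum(t.dropped_flag for t in desk_trials)
    assert report["cycles_kept"] == len(segments)
    assert report["cycles_kept"] > 0
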