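"""Division-cycle segmentation, detrending, phase resampling, profiles,
null controls and clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import CubicSpline

from nadhcycle.cycles import (
    CycleProfileMatrix,
    SplineConfig,
    analyze_cycles,
    build_cycle_matrix,
    central_profile,
    cluster_cycles,
    extend_cycle,
    fixed_division_null,
    flatness,
    frame_shift_test,
    linear_detrend,
    pattern_metric,
    resample_cycle,
    segment_cycles,
    smoothing_spline,
    spline_detrend,
)
from nadhcycle.errors import DataError
from nadhcycle.synthetic import SimConfig, simulate_lineage
from nadhcycle.trajectory import CellTrack


def _track(n=61, divisions=(), values=None, dt=10.0):
    t = np.arange(n) * dt
    y = np.full(n, 100.0) if values is None else np.asarray(values, dtype=float)
    return CellTrack(1, t, np.ones(n), y, np.asarray(divisions, dtype=int))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_segment_cycles_division_frame_is_last_frame():
    cycles = segment_cycles(_track(divisions=(10, 20, 30)))
    assert [(c.start_frame, c.end_frame) for c in cycles] == [(11, 20), (21, 30)]
    assert cycles[0].duration_min == pytest.approx(90.0)


def test_segment_cycles_needs_two_divisions():
    assert segment_cycles(_track(divisions=(10,))) == []
    assert segment_cycles(_track()) == []


def test_segment_cycles_partials():
    cycles, head, tail = segment_cycles(_track(n=40, divisions=(10, 20)), return_partials=True)
    assert (head.start_frame, head.end_frame) == (0, 10)
    assert (tail.start_frame, tail.end_frame) == (21, 39)
    assert len(cycles) == 1


@settings(deadline=None, derandomize=True)
@given(st.sets(st.integers(1, 58), min_size=2, max_size=10))
def test_segment_cycles_partition_interior_frames(division_set):
    divisions = sorted(division_set)
    cycles = segment_cycles(_track(n=60, divisions=divisions))
    covered = [f for c in cycles for f in range(c.start_frame, c.end_frame + 1)]
    assert len(covered) == len(set(covered))  # disjoint
    assert set(covered) == set(range(divisions[0] + 1, divisions[-1] + 1))


# ---------------------------------------------------------------------------
# smoothing-spline detrending
# ---------------------------------------------------------------------------

def _roughness(x, v):
    """integral of s'' squared for the natural cubic interpolant of (x, v)."""
    cs = CubicSpline(x, v, bc_type="natural")
    m = cs(x, 2)
    h = np.diff(x)
    return float(np.sum(h / 3.0 * (m[:-1] ** 2 + m[:-1] * m[1:] + m[1:] ** 2)))


def _objective(x, y, v, p):
    return p * float(np.sum((y - v) ** 2)) + (1 - p) * _roughness(x, v)


def test_smoothing_spline_minimizes_penalized_objective(rng):
    """Variational oracle: the fitted knot values minimize
    p.sum((y-s)^2) + (1-p).integral(s'')^2 over natural cubic splines —
    every random perturbation increases the objective."""
    y = 100 + np.cumsum(rng.normal(0, 2, 40)) + 5 * np.sin(np.arange(40) / 3)
    x = np.arange(40.0)
    p = 0.004
    fitted = smoothing_spline(y, SplineConfig(smoothing_p=p))
    j0 = _objective(x, y, fitted, p)
    for _ in range(25):
        perturbed = fitted + rng.normal(0, 0.05, 40)
        assert _objective(x, y, perturbed, p) > j0
    # finite-difference gradient vanishes at the fit
    for i in (0, 13, 39):
        eps = 1e-5
        up = fitted.copy()
        up[i] += eps
        down = fitted.copy()
        down[i] -= eps
        grad = (_objective(x, y, up, p) - _objective(x, y, down, p)) / (2 * eps)
        assert abs(grad) < 1e-4


def test_spline_detrend_constant_series():
    assert np.allclose(spline_detrend(np.full(20, 37.0)), 1.0)


def test_spline_detrend_interpolating_limit():
    rng = np.random.default_rng(3)
    y = rng.uniform(90, 110, 25)
    out = spline_detrend(y, SplineConfig(smoothing_p=1 - 1e-12))
    assert np.allclose(out, 1.0, atol=1e-6)


def test_spline_detrend_recovers_cycles_on_slow_trend():
    """Unit-mean cycle signal times a slow exponential trend: the quotient
    recovers the cycle signal within 2% RMS (interior frames)."""
    n = 61
    t = np.arange(n)
    trend = 100 * np.exp(0.003 * t)  # time constant ~330 frames >> cycle
    cycle_signal = 1 + 0.05 * np.sin(2 * np.pi * t / 8.0)
    out = spline_detrend(trend * cycle_signal)
    rms = np.sqrt(np.mean((out[5:-5] - cycle_signal[5:-5]) ** 2))
    assert rms < 0.02


def test_spline_detrend_scale_invariant(rng):
    y = rng.uniform(90, 110, 30)
    assert np.allclose(spline_detrend(y), spline_detrend(1000 * y))


def test_spline_detrend_validation():
    with pytest.raises(DataError):
        spline_detrend(np.ones(5))
    with pytest.raises(DataError):
        SplineConfig(smoothing_p=0.0)
    # spline through zero -> quotient undefined
    y = np.linspace(10, -10, 20)
    with pytest.raises(DataError):
        spline_detrend(y)


# ---------------------------------------------------------------------------
# linear detrending
# ---------------------------------------------------------------------------

def test_linear_detrend_exact_line_gives_zeros():
    t = np.arange(10.0)
    assert np.allclose(linear_detrend(t, 3.0 + 2.0 * t), 0.0)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=3, max_size=25))
def test_linear_detrend_endpoints_always_zero(values):
    out = linear_detrend(np.arange(len(values), dtype=float), values)
    assert out[0] == pytest.approx(0.0, abs=1e-9)
    assert out[-1] == pytest.approx(0.0, abs=1e-9)


def test_linear_detrend_triangle_peak():
    y = np.array([2.0, 6.0, 10.0, 6.0, 4.0])  # endpoints 2 and 4, peak 10
    out = linear_detrend(np.arange(5.0), y)
    assert out[2] == pytest.approx(10.0 - (2.0 + 4.0) / 2.0)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_resample_identity_on_21_even_points(rng):
    y = rng.uniform(0, 1, 21)
    assert np.allclose(resample_cycle(y, np.linspace(0, 200, 21)), y)


@pytest.mark.parametrize("n", range(5, 31))
def test_resample_always_21_points(n, rng):
    assert resample_cycle(rng.uniform(0, 1, n)).size == 21


def test_resample_linear_ramp_stays_linear():
    out = resample_cycle(np.linspace(2.0, 7.0, 9))
    assert np.allclose(out, np.linspace(2.0, 7.0, 21))


@settings(deadline=None, derandomize=True)
@given(st.floats(-5, 5), st.floats(0.1, 10))
def test_resample_commutes_with_affine_transform(offset, scale):
    rng = np.random.default_rng(5)
    y = rng.uniform(0, 1, 13)
    assert np.allclose(
        resample_cycle(scale * y + offset), scale * resample_cycle(y) + offset
    )


# ---------------------------------------------------------------------------
# adjacent-cycle extension
# ---------------------------------------------------------------------------

def test_extend_zero_fraction_equals_resample(rng):
    t = np.arange(40.0) * 10
    y = rng.uniform(0.9, 1.1, 40)
    ext = extend_cycle(t, y, 10, 20, fraction=0.0)
    assert np.allclose(ext.values, resample_cycle(y[10:21], t[10:21]))


def test_extend_ten_percent_gives_25_values(rng):
    t = np.arange(40.0) * 10
    y = rng.uniform(0.9, 1.1, 40)
    ext = extend_cycle(t, y, 10, 20, fraction=0.10)
    assert ext.values.size == 25
    assert (ext.n_left, ext.n_right) == (2, 2)
    # core agrees with the plain resample
    assert np.allclose(ext.values[2:-2], resample_cycle(y[10:21], t[10:21]))


def test_extend_flat_input_all_ones():
    t = np.arange(40.0) * 10
    ext = extend_cycle(t, np.ones(40), 10, 20, fraction=0.10)
    assert np.allclose(ext.values, 1.0)


def test_extend_one_sided_at_track_edge():
    t = np.arange(15.0) * 10
    ext = extend_cycle(t, np.ones(15), 0, 10, fraction=0.10)
    assert ext.n_left == 0 and ext.n_right == 2


# ---------------------------------------------------------------------------
# profiles, flatness, pattern
# ---------------------------------------------------------------------------

def _matrix(values, method="spline_quotient"):
    import pandas as pd

    values = np.asarray(values, dtype=float)
    return CycleProfileMatrix(
        values, np.linspace(0, 1, values.shape[1]), pd.DataFrame(), method
    )


def test_central_profile_identical_rows():
    row = np.linspace(0.9, 1.1, 21)
    m = _matrix(np.tile(row, (5, 1)))
    assert np.allclose(central_profile(m), row)


def test_central_profile_median_matches_sort_oracle(rng):
    values = rng.uniform(0, 2, (3, 21))
    m = _matrix(values)
    expected = np.sort(values, axis=0)[1]
    assert np.allclose(central_profile(m), expected)
    assert np.allclose(central_profile(m, "mean"), values.mean(axis=0))


def test_flatness_trivials_and_oracle(rng):
    assert flatness(np.ones(21)) == 0.0
    assert flatness([1.0, 1.02, 0.99]) == pytest.approx(0.02)
    p = rng.uniform(0.8, 1.2, 21)
    assert flatness(p) == pytest.approx(np.max(np.abs(p - 1.0)))
    assert flatness(p, null_level=0.0) == pytest.approx(np.max(np.abs(p)))


def test_pattern_metric_cases():
    monotone = pattern_metric(np.linspace(0.9, 1.1, 21))
    assert not monotone.is_increase_drop  # argmax on the boundary
    bump = np.ones(21)
    bump[13] = 1.05
    m = pattern_metric(bump, threshold=0.01)
    assert m.peak_phase == pytest.approx(0.65)
    assert m.amplitude == pytest.approx(0.05)
    assert m.is_increase_drop
    flat = pattern_metric(np.ones(21))
    assert flat.amplitude == 0.0 and not flat.is_increase_drop


# ---------------------------------------------------------------------------
# null controls
# ---------------------------------------------------------------------------

def test_fixed_null_six_durations_and_flat_input(default_tracks):
    flat_tracks = [
        CellTrack(t.track_id, t.time_min, t.area, np.full(t.n_frames, 80.0), t.division_frames)
        for t in default_tracks
    ]
    profiles = fixed_division_null(flat_tracks)
    assert sorted(profiles) == [60.0, 70.0, 80.0, 90.0, 100.0, 110.0]
    for profile in profiles.values():
        assert np.allclose(profile, 1.0)


def test_fixed_null_flat_on_amplitude_zero_data():
    tracks = simulate_lineage(SimConfig(n_tracks=30, cycle_amplitude=0.0, seed=21))
    profiles = fixed_division_null(tracks)
    for profile in profiles.values():
        assert flatness(profile) < 0.02  # sampling noise only


def test_frame_shift_zero_max_shift_reproduces_profile(default_tracks):
    matrix = build_cycle_matrix(default_tracks)
    profile = central_profile(matrix)
    results = frame_shift_test(default_tracks, n_tests=2, seed=0, max_shift=0)
    for res in results:
        assert np.allclose(res.profile, profile)
        assert res.n_cycles == matrix.n_cycles


def test_frame_shift_default_count_and_determinism(default_tracks):
    a = frame_shift_test(default_tracks, seed=4)
    b = frame_shift_test(default_tracks, seed=4)
    assert len(a) == 10
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.profile, rb.profile)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_cluster_identical_rows_zero_inertia():
    m = _matrix(np.tile(np.linspace(0.9, 1.1, 21), (8, 1)))
    res = cluster_cycles(m, k=2, seed=0)
    assert res.inertia == pytest.approx(0.0)


def test_cluster_recovers_separated_archetypes(rng):
    early = np.ones(21)
    early[5] = 2.0
    late = np.ones(21)
    late[15] = 2.0
    values = np.vstack([np.tile(early, (50, 1)), np.tile(late, (50, 1))])
    values = values + rng.normal(0, 0.01, values.shape)
    m = _matrix(values)
    res = cluster_cycles(m, k=2, seed=0)
    first, second = res.labels[:50], res.labels[50:]
    assert len(set(first)) == 1 and len(set(second)) == 1
    assert first[0] != second[0]
    assert res.fraction_second_half == pytest.approx(0.5)


def test_cluster_requires_enough_rows():
    with pytest.raises(DataError):
        cluster_cycles(_matrix(np.ones((3, 21))), k=4)


def test_cluster_fraction_invariant_to_row_order(rng):
    values = rng.uniform(0.9, 1.1, (40, 21))
    frac = cluster_cycles(_matrix(values), k=4, seed=1).fraction_second_half
    shuffled = values[rng.permutation(40)]
    assert cluster_cycles(_matrix(shuffled), k=4, seed=1).fraction_second_half == frac


# ---------------------------------------------------------------------------
# cross-method agreement
# ---------------------------------------------------------------------------

def test_both_normalizations_agree_on_pattern(default_tracks):
    spline_report = analyze_cycles(default_tracks, n_shift_tests=0, seed=1)
    linear_report = analyze_cycles(
        default_tracks, method="linear_residual", n_shift_tests=0, seed=1
    )
    assert spline_report.metric.is_increase_drop == linear_report.metric.is_increase_drop
    # and both place the peak in the second half of the cycle
    assert spline_report.metric.peak_phase > 0.5
    assert linear_report.metric.peak_phase > 0.5
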