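"""Synthetic single-cell NAD(P)H time-lapse data.

The generator emulates the statistical structure the downstream analysis
assumes for *E. coli* imaged every few minutes under 365 nm excitation:

* log-normal interdivision times, calibrated so that a configurable fraction
  (default 80%) falls in a 60-110 min window around a median of 82 min;
* per-frame ROI areas growing exponentially at a basal rate (default
  0.6 h^-1) reduced by an exposure-energy/interval-dependent photodamage
  factor, the observed area halving at each division (one sister followed);
* fluorescence intensity = slow multiplicative drift x smooth unimodal
  "increase-drop" cycle shape (peak in the second half of the cycle) x
  i.i.d. multiplicative frame noise;
* metabolic perturbation experiments with a tracer-dye channel: a glucose
  upshift whose intensity doubles within 20 min of medium arrival, and an
  H2O2 challenge whose intensity starts declining 30 min after arrival;
* rendered 16-bit-style raw images: CCD baseline (default 500 AU) + smooth
  uneven illumination x background + cell signal at a fixed fraction
  (default 45%) of the local background, with matching blank positions and
  ROI label masks.

All operations are bit-reproducible for a fixed seed and configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.stats import norm

from .correction import ImageStack
from .errors import CalibrationError, ConfigError
from .trajectory import CellTrack

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "PhotodamageModel",
    "SceneConfig",
    "PerturbationResult",
    "RenderResult",
    "calibrate_division_sigma",
    "simulate_division_times",
    "default_photodamage_model",
    "photodamage_reduction",
    "cycle_shape",
    "simulate_lineage",
    "simulate_perturbation",
    "simulate_exposure_ladder",
    "render_frames",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Lineage-simulation parameters.

    ``division_time_sigma=None`` means "calibrate the log-normal spread so
    that ``division_window_fraction`` of interdivision times falls inside
    ``division_window_min``" (the default reproduces 80% in 60-110 min).
    ``cycle_amplitude`` is the peak-to-trough fraction of the mean intensity;
    no measured value for it exists, so the 5% default is an exposed guess.
    """

    frame_interval_min: float = 10.0
    duration_h: float = 10.0
    n_tracks: int = 20
    division_time_median_min: float = 82.0
    division_time_sigma: float | None = None
    division_window_min: tuple[float, float] = (60.0, 110.0)
    division_window_fraction: float = 0.80
    cycle_amplitude: float = 0.05
    cycle_peak_phase: float = 0.65
    drift_sd: float = 0.05
    frame_noise_cv: float = 0.05
    basal_growth_rate_h: float = 0.6
    base_intensity_au: float = 100.0
    initial_area_px: float = 150.0
    loss_prob_per_division: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        positives = {
            "frame_interval_min": self.frame_interval_min,
            "duration_h": self.duration_h,
            "n_tracks": self.n_tracks,
            "division_time_median_min": self.division_time_median_min,
            "base_intensity_au": self.base_intensity_au,
            "initial_area_px": self.initial_area_px,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ConfigError(f"{name} must be > 0, got {value}")
        non_negatives = {
            "cycle_amplitude": self.cycle_amplitude,
            "drift_sd": self.drift_sd,
            "frame_noise_cv": self.frame_noise_cv,
            "basal_growth_rate_h": self.basal_growth_rate_h,
            "loss_prob_per_division": self.loss_prob_per_division,
        }
        if self.division_time_sigma is not None:
            non_negatives["division_time_sigma"] = self.division_time_sigma
        for name, value in non_negatives.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if not 0.0 < self.cycle_peak_phase < 1.0:
            raise ConfigError(
                f"cycle_peak_phase must lie in (0, 1), got {self.cycle_peak_phase}"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h * 60.0 / self.frame_interval_min)) + 1

    def resolved_sigma(self) -> float:
        if self.division_time_sigma is not None:
            return self.division_time_sigma
        lo, hi = self.division_window_min
        return calibrate_division_sigma(
            self.division_time_median_min, self.division_window_fraction, lo, hi
        )


@dataclass(frozen=True)
class PhotodamageModel:
    """Dose-response of growth-rate reduction on exposure energy and interval.

    ``anchors`` are ``(energy_uJ, interval_min, fractional_reduction)`` rows.
    The reduction is piecewise-linear in energy within each interval class and
    linearly interpolated between interval classes; energies above the largest
    anchor are clamped (with a logged warning), as are intervals outside the
    anchored range.
    """

    anchors: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ConfigError("photodamage model needs at least one anchor")
        by_interval = self._by_interval()
        for interval, (energies, reductions) in by_interval.items():
            if np.any((reductions < 0) | (reductions > 1)):
                raise ConfigError("fractional reductions must lie in [0, 1]")
            if np.any(np.diff(reductions) < 0):
                raise ConfigError(
                    f"reduction must be non-decreasing in energy (interval {interval})"
                )
            if energies[0] == 0 and reductions[0] != 0:
                raise ConfigError("reduction at zero energy must be 0")

    def _by_interval(self) -> dict[float, tuple[np.ndarray, np.ndarray]]:
        grouped: dict[float, list[tuple[float, float]]] = {}
        for energy, interval, red in self.anchors:
            grouped.setdefault(float(interval), []).append((float(energy), float(red)))
        out = {}
        for interval, rows in grouped.items():
            rows.sort()
            e = np.array([r[0] for r in rows])
            red = np.array([r[1] for r in rows])
            out[interval] = (e, red)
        return out

    def reduction(self, energy_uJ: float, interval_min: float) -> float:
        if energy_uJ < 0:
            raise ConfigError(f"energy must be >= 0, got {energy_uJ}")
        if energy_uJ == 0:
            return 0.0
        by_interval = self._by_interval()
        intervals = np.array(sorted(by_interval))
        per_class = []
        for interval in intervals:
            energies, reds = by_interval[interval]
            if energy_uJ > energies[-1]:
                logger.warning(
                    "energy %.3g uJ above largest anchor %.3g uJ; clamping",
                    energy_uJ,
                    energies[-1],
                )
            per_class.append(float(np.interp(energy_uJ, energies, reds)))
        return float(np.interp(interval_min, intervals, per_class))


def default_photodamage_model() -> PhotodamageModel:
    """Default anchor table.

    Only two anchors are measured values (10% reduction at 9 uJ/15 min, 89%
    at 56 uJ/5 min); up to 9 uJ all intervals coincide, and the remaining
    anchors follow the qualitative dose-response shape (5-min interval
    aggravates damage most) by monotone interpolation.  They are defaults,
    not assertions.
    """
    anchors = []
    table = {
        5.0: [(0, 0.0), (9, 0.10), (22, 0.45), (34, 0.65), (45, 0.80), (56, 0.89)],
        10.0: [(0, 0.0), (9, 0.10), (22, 0.32), (34, 0.46), (45, 0.56), (56, 0.66)],
        15.0: [(0, 0.0), (9, 0.10), (22, 0.26), (34, 0.38), (45, 0.48), (56, 0.58)],
    }
    for interval, rows in table.items():
        for energy, red in rows:
            anchors.append((float(energy), interval, red))
    return PhotodamageModel(tuple(anchors))


def photodamage_reduction(
    model: PhotodamageModel, energy_uJ: float, interval_min: float
) -> float:
    """Fractional growth-rate reduction for one exposure setting."""
    return model.reduction(energy_uJ, interval_min)


@dataclass(frozen=True)
class SceneConfig:
    """Image-rendering parameters.

    ``illumination_coeffs`` are 2-D polynomial coefficients evaluated on
    normalized coordinates in [-1, 1]^2 (mean roughly 1); the raw pixel model
    is ``baseline + illumination * background_level (+ cell signal) + noise``
    with cell signal ``cell_signal_ratio x local background x normalized
    track intensity``.
    """

    image_shape: tuple[int, int] = (256, 256)
    background_level: float = 400.0
    illumination_coeffs: tuple[tuple[float, ...], ...] = ((1.0, 0.08), (0.12, 0.0))
    cell_signal_ratio: float = 0.45
    baseline: float = 500.0
    read_noise_sd: float = 2.0
    shot_noise: bool = False
    n_blank_positions: int = 1
    cell_radius_px: float = 3.0
    centers: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ConfigError("baseline must be >= 0")
        if self.background_level <= 0:
            raise ConfigError("background_level must be > 0")
        if not 1 <= self.n_blank_positions <= 3:
            raise ConfigError("n_blank_positions must be in 1..3")
        if self.cell_signal_ratio < 0:
            raise ConfigError("cell_signal_ratio must be >= 0")

    def illumination_field(self) -> np.ndarray:
        h, w = self.image_shape
        v = np.linspace(-1.0, 1.0, h)
        u = np.linspace(-1.0, 1.0, w)
        uu, vv = np.meshgrid(u, v)
        coeffs = np.asarray(self.illumination_coeffs, dtype=float)
        fld = npoly.polyval2d(uu, vv, coeffs)
        if np.any(fld <= 0):
            raise ConfigError("illumination field must be strictly positive")
        return fld


# --------------------------------------------------------------------------
# division-time law
# --------------------------------------------------------------------------

def _window_fraction(sigma: float, median: float, lo: float, hi: float) -> float:
    upper = 1.0 if not math.isfinite(hi) else norm.cdf(math.log(hi / median) / sigma)
    lower = 0.0 if lo == 0 else norm.cdf(math.log(lo / median) / sigma)
    return float(upper - lower)


@lru_cache(maxsize=64)
def calibrate_division_sigma(
    median_min: float = 82.0,
    target_fraction: float = 0.80,
    lo: float = 60.0,
    hi: float = 110.0,
    bracket: tuple[float, float] = (1e-3, 10.0),
) -> float:
    """Log-scale sigma of a log-normal interdivision-time law.

    Solves ``P(lo <= T <= hi) = target_fraction`` for ``T`` log-normal with
    the given median, by root finding on the closed-form CDF.  The window
    fraction decreases monotonically in sigma, so the root is unique when it
    exists within the search bracket; otherwise (e.g. unconstrained or
    near-degenerate windows) a :class:`CalibrationError` is raised.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ConfigError("target_fraction must lie in (0, 1)")
    if not 0.0 <= lo < median_min < hi:
        raise ConfigError("need 0 <= lo < median < hi")

    def f(sigma: float) -> float:
        return _window_fraction(sigma, median_min, lo, hi) - target_fraction

    a, b = bracket
    fa, fb = f(a), f(b)
    if fa * fb > 0:
        raise CalibrationError(
            f"no root in search bracket {bracket}: window fraction spans "
            f"[{fb + target_fraction:.4g}, {fa + target_fraction:.4g}], "
            f"target {target_fraction}"
        )
    sigma = brentq(f, a, b, xtol=1e-12)
    assert abs(f(sigma)) < 1e-6
    return float(sigma)


def simulate_division_times(
    n: int, config: SimConfig | None = None, seed: int | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. log-normal interdivision times (minutes)."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    cfg = config if config is not None else SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sigma = cfg.resolved_sigma()
    return rng.lognormal(mean=math.log(cfg.division_time_median_min), sigma=sigma, size=n)


# --------------------------------------------------------------------------
# intra-cycle shape
# --------------------------------------------------------------------------

def cycle_shape(
    amplitude: float = 0.05, peak_phase: float = 0.65
) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth unimodal "increase-drop" intensity profile over one cycle.

    Piecewise-cubic (monotone Hermite) with trough value ``1 - A/2`` at both
    cycle boundaries, peak value ``1 + A/2`` at ``peak_phase`` (zero slope
    there), and low shoulders at 60% of the rise and 55% of the fall keeping
    the peak well localized; the curve is rescaled to unit mean over the
    cycle (the rescaling factor is exact: the piecewise cubic is integrated
    analytically).
    """
    if not 0.0 < peak_phase < 1.0:
        raise ConfigError("peak_phase must lie in (0, 1)")
    if amplitude < 0:
        raise ConfigError("amplitude must be >= 0")
    if amplitude == 0:
        return lambda phase: np.ones_like(np.asarray(phase, dtype=float))
    lo = 1.0 - amplitude / 2
    hi = 1.0 + amplitude / 2
    shoulder = lo + 0.15 * amplitude
    knots = np.array(
        [0.0, 0.6 * peak_phase, peak_phase, peak_phase + 0.55 * (1 - peak_phase), 1.0]
    )
    values = np.array([lo, shoulder, hi, shoulder, lo])
    spline = PchipInterpolator(knots, values)
    anti = spline.antiderivative()
    mean = float(anti(1.0) - anti(0.0))

    def shape(phase):
        p = np.clip(np.asarray(phase, dtype=float), 0.0, 1.0)
        return spline(p) / mean

    return shape


# --------------------------------------------------------------------------
# lineage simulation
# --------------------------------------------------------------------------

def _draw_division_schedule(
    rng: np.random.Generator, cfg: SimConfig, sigma: float, span_min: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative division times and per-cycle durations covering the span.

    The cell's age at the start of observation is uniform over its first
    cycle, so the simulated population is asynchronous (as cells loaded onto
    a device are); division times may therefore start anywhere in (0, D0).
    """
    log_median = math.log(cfg.division_time_median_min)
    durations: list[float] = [float(rng.lognormal(mean=log_median, sigma=sigma))]
    age0 = float(rng.uniform(0.0, durations[0]))
    total = durations[0] - age0
    while total <= span_min:
        d = float(rng.lognormal(mean=log_median, sigma=sigma))
        durations.append(d)
        total += d
    durations_arr = np.array(durations)
    div_times = np.cumsum(durations_arr) - age0
    return div_times, durations_arr


def simulate_lineage(
    config: SimConfig,
    damage: PhotodamageModel | None = None,
    exposure: tuple[float, float] | None = None,
    seed: int | None = None,
) -> list[CellTrack]:
    """Simulate ``config.n_tracks`` followed lineages.

    Growth rate is ``basal x (1 - reduction)`` where the reduction comes from
    the photodamage model at the given ``(energy_uJ, interval_min)`` exposure
    (0 if either is omitted).  After each division one of the two equal
    sisters is followed (chosen uniformly at random).
    """
    reduction = 0.0
    if damage is not None and exposure is not None:
        reduction = damage.reduction(*exposure)
    rate = config.basal_growth_rate_h * (1.0 - reduction)
    sigma = config.resolved_sigma()
    shape = cycle_shape(config.cycle_amplitude, config.cycle_peak_phase)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    dt = config.frame_interval_min
    n_frames = config.n_frames
    t = np.arange(n_frames) * dt
    t_h = t / 60.0
    span = t[-1]

    tracks: list[CellTrack] = []
    for track_id in range(1, config.n_tracks + 1):
        div_times, durations = _draw_division_schedule(rng, config, sigma, span)
        observed = div_times[div_times < span + dt]
        division_frames = np.floor(observed / dt).astype(int)
        division_frames = division_frames[division_frames < n_frames]
        division_frames = np.unique(division_frames)
        # which sister is followed: drawn per division, no observable effect
        # because sisters are equal halves
        rng.integers(0, 2, size=division_frames.size)

        frames = np.arange(n_frames)
        n_before = np.searchsorted(division_frames, frames, side="left")
        area = config.initial_area_px * np.exp(rate * t_h) * 0.5 ** n_before

        # continuous cycle phase
        cycle_idx = np.searchsorted(div_times, t, side="right")
        births = (div_times - durations)[cycle_idx]
        phase = (t - births) / durations[cycle_idx]

        increments = rng.normal(0.0, config.drift_sd * math.sqrt(dt / 60.0), n_frames - 1)
        trend = np.exp(np.concatenate(([0.0], np.cumsum(increments))))
        noise = 1.0 + rng.normal(0.0, config.frame_noise_cv, n_frames)
        intensity = config.base_intensity_au * trend * shape(phase) * noise

        end = n_frames
        if config.loss_prob_per_division > 0 and division_frames.size:
            lost = rng.random(division_frames.size) < config.loss_prob_per_division
            if np.any(lost):
                end = int(division_frames[np.nonzero(lost)[0][0]]) + 1
        tracks.append(
            CellTrack(
                track_id=track_id,
                time_min=t[:end],
                area=area[:end],
                intensity=intensity[:end],
                division_frames=division_frames[division_frames < end],
            )
        )
    return tracks


# --------------------------------------------------------------------------
# perturbation experiments
# --------------------------------------------------------------------------

@dataclass
class PerturbationResult:
    """Tracks plus the tracer-dye channel of a medium-switch experiment."""

    tracks: list[CellTrack]
    dye: np.ndarray
    frame_times: np.ndarray
    switch_frame: int
    kind: str


def simulate_perturbation(
    kind: str,
    config: SimConfig | None = None,
    seed: int | None = None,
    switch_time_min: float | None = None,
    response_fold: float = 2.0,
    response_horizon_min: float = 20.0,
    rise_tau_min: float = 10.0,
    h2o2_delay_min: float = 30.0,
    h2o2_decay_per_min: float = 0.01,
    dye_high: float = 100.0,
    dye_low: float = 10.0,
    dye_noise_sd: float = 0.5,
) -> PerturbationResult:
    """Simulate a glucose-upshift or H2O2 perturbation experiment.

    ``glucose_upshift``: starved cells at a low intensity plateau; after the
    new medium arrives (dye channel descends) intensity rises saturating so
    that it reaches ``response_fold`` x baseline exactly ``response_horizon_min``
    minutes after arrival, and cells start growing.  ``h2o2``: growing cells;
    the dye channel ascends on arrival and intensity stays flat for
    ``h2o2_delay_min`` minutes, then declines exponentially.  Setting
    ``response_fold=1`` (or ``h2o2_decay_per_min=0``) gives flat trajectories.
    """
    if kind not in ("glucose_upshift", "h2o2"):
        raise ConfigError(f"unknown perturbation kind {kind!r}")
    cfg = config if config is not None else SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    dt = cfg.frame_interval_min
    n_frames = cfg.n_frames
    t = np.arange(n_frames) * dt
    if switch_time_min is None:
        switch_time_min = 120.0 if kind == "glucose_upshift" else 210.0
    switch_frame = int(round(switch_time_min / dt))
    if not 3 < switch_frame < n_frames - max(3, int(response_horizon_min / dt) + 1):
        raise ConfigError("switch time leaves too few pre- or post-switch frames")
    t_arr = switch_frame * dt

    # dye channel: steep logistic centered half a frame before arrival, so
    # the first frame at/after arrival is already past the midpoint
    center = t_arr - 0.5 * dt
    width = dt / 6.0
    step = 1.0 / (1.0 + np.exp(-(t - center) / width))
    if kind == "glucose_upshift":
        dye = dye_high + (dye_low - dye_high) * step
    else:
        dye = dye_low + (dye_high - dye_low) * step
    dye = dye + rng.normal(0.0, dye_noise_sd, n_frames)

    tracks: list[CellTrack] = []
    base = 0.5 * cfg.base_intensity_au if kind == "glucose_upshift" else cfg.base_intensity_au
    for track_id in range(1, cfg.n_tracks + 1):
        rel = t - t_arr
        if kind == "glucose_upshift":
            sat = 1.0 - np.exp(-np.maximum(rel, 0.0) / rise_tau_min)
            sat_at_horizon = 1.0 - math.exp(-response_horizon_min / rise_tau_min)
            fold_inf = 1.0 + (response_fold - 1.0) / sat_at_horizon
            profile = 1.0 + (fold_inf - 1.0) * sat
            area = cfg.initial_area_px * np.exp(
                cfg.basal_growth_rate_h * np.maximum(rel, 0.0) / 60.0
            )
        else:
            decline = np.exp(
                -h2o2_decay_per_min * np.maximum(rel - h2o2_delay_min, 0.0)
            )
            profile = decline
            area = cfg.initial_area_px * np.exp(cfg.basal_growth_rate_h * t / 60.0)
        noise = 1.0 + rng.normal(0.0, cfg.frame_noise_cv, n_frames)
        intensity = base * profile * noise
        tracks.append(
            CellTrack(track_id=track_id, time_min=t, area=area, intensity=intensity)
        )
    return PerturbationResult(tracks, dye, t, switch_frame, kind)


# --------------------------------------------------------------------------
# exposure ladder (signal vs background)
# --------------------------------------------------------------------------

def simulate_exposure_ladder(
    energies: Sequence[float] = (9.0, 22.0, 34.0, 45.0, 56.0),
    n_cells: int = 20,
    scene: SceneConfig | None = None,
    noise_cv: float = 0.05,
    reference_energy: float = 45.0,
    seed: int | None = 0,
):
    """Per-cell (background, signal) intensity pairs across exposure energies.

    Background intensity scales linearly with exposure energy
    (``background_level`` at ``reference_energy``); the true cell signal is
    ``cell_signal_ratio`` x background, and both measurements carry
    multiplicative noise with the given CV.  Returns a DataFrame with columns
    ``energy_uJ``, ``background_au``, ``signal_au``.
    """
    import pandas as pd

    sc = scene if scene is not None else SceneConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for energy in energies:
        bg_true = sc.background_level * energy / reference_energy
        bg = bg_true * (1.0 + rng.normal(0.0, noise_cv, n_cells))
        sig = sc.cell_signal_ratio * bg_true * (1.0 + rng.normal(0.0, noise_cv, n_cells))
        for b, s in zip(bg, sig):
            rows.append({"energy_uJ": energy, "background_au": b, "signal_au": s})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------

@dataclass
class RenderResult:
    """Rendered experimental stack, blank stack(s) and per-frame label masks."""

    experimental: ImageStack
    blanks: list[ImageStack]
    masks: np.ndarray  # (T, H, W) int32, 0 = background, label = track_id


def _capsule_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle: float,
    area: float,
    radius: float,
) -> np.ndarray:
    """Boolean mask of a capsule (rectangle + half-disks) of the given area."""
    h, w = shape
    rect_len = max(0.0, (area - math.pi * radius**2) / (2.0 * radius))
    dy, dx = math.sin(angle), math.cos(angle)
    half = rect_len / 2.0
    p0 = np.array([center[0] - half * dy, center[1] - half * dx])
    p1 = np.array([center[0] + half * dy, center[1] + half * dx])
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.stack([rr, cc], axis=-1).astype(float)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    if seg_len2 == 0:
        dist = np.hypot(pts[..., 0] - p0[0], pts[..., 1] - p0[1])
    else:
        tproj = np.clip(((pts - p0) @ seg) / seg_len2, 0.0, 1.0)
        closest = p0 + tproj[..., None] * seg
        dist = np.hypot(pts[..., 0] - closest[..., 0], pts[..., 1] - closest[..., 1])
    return dist <= radius


def _place_cells(
    tracks: Sequence[CellTrack],
    scene: SceneConfig,
    rng: np.random.Generator,
) -> list[tuple[tuple[float, float], float]]:
    """Choose non-overlapping (center, angle) per track, sized at max area."""
    h, w = scene.image_shape
    placements: list[tuple[tuple[float, float], float]] = []
    extents = []
    for track in tracks:
        max_area = float(np.max(track.area))
        rect_len = max(0.0, (max_area - math.pi * scene.cell_radius_px**2) / (2 * scene.cell_radius_px))
        extent = rect_len / 2.0 + scene.cell_radius_px
        extents.append(extent)
        if 2 * extent >= min(h, w) - 2:
            raise ConfigError(
                f"track {track.track_id} too large for image (extent {extent:.1f} px)"
            )
    fixed_centers = scene.centers is not None
    for i, track in enumerate(tracks):
        extent = extents[i]
        if fixed_centers:
            candidates = [(scene.centers[i], float(rng.uniform(0, math.pi)))]
        else:
            candidates = [
                (
                    (
                        float(rng.uniform(extent + 1, h - extent - 1)),
                        float(rng.uniform(extent + 1, w - extent - 1)),
                    ),
                    float(rng.uniform(0, math.pi)),
                )
                for _ in range(200)
            ]
        placed = False
        for center, angle in candidates:
            ok = True
            for j, (other_center, _) in enumerate(placements):
                min_sep = extent + extents[j] + 2.0
                if math.hypot(center[0] - other_center[0], center[1] - other_center[1]) < min_sep:
                    ok = False
                    break
            if ok:
                placements.append((center, angle))
                placed = True
                break
        if not placed:
            raise ConfigError(
                "overlapping cells: could not place all tracks without overlap"
            )
    return placements


def render_frames(
    tracks: Sequence[CellTrack],
    scene: SceneConfig | None = None,
    seed: int | None = 0,
) -> RenderResult:
    """Render raw fluorescence frames, blank position(s) and ROI label masks.

    Raw pixel = ``baseline + illumination x background_level`` plus, inside a
    cell, ``cell_signal_ratio x local background x normalized track
    intensity`` (the track intensity divided by its own mean), plus optional
    Gaussian read noise and Poisson shot noise.  Blank stacks use the same
    illumination and noise model without cells.  Frames are float64; quantize
    when writing TIFF.
    """
    sc = scene if scene is not None else SceneConfig()
    rng = np.random.default_rng(seed)
    illum = sc.illumination_field()
    background = illum * sc.background_level

    if tracks:
        n_frames = tracks[0].n_frames
        times = tracks[0].time_min
        for track in tracks:
            if track.n_frames != n_frames:
                raise ConfigError("all tracks must cover the same frames to render")
            if track.track_id < 1:
                raise ConfigError("track_id must be >= 1 to serve as mask label")
        placements = _place_cells(tracks, sc, rng)
        norm_intensity = [track.intensity / float(np.mean(track.intensity)) for track in tracks]
    else:
        n_frames, times, placements, norm_intensity = 1, np.array([0.0]), [], []

    h, w = sc.image_shape
    exp_frames = np.empty((n_frames, h, w))
    masks = np.zeros((n_frames, h, w), dtype=np.int32)
    for f in range(n_frames):
        frame = sc.baseline + background.copy()
        for track, (center, angle), norm in zip(tracks, placements, norm_intensity):
            cell = _capsule_mask(sc.image_shape, center, angle, float(track.area[f]), sc.cell_radius_px)
            if np.any(masks[f][cell] != 0):
                raise ConfigError("overlapping cells in rendered frame")
            masks[f][cell] = track.track_id
            frame[cell] += sc.cell_signal_ratio * background[cell] * norm[f]
        if sc.shot_noise:
            frame = sc.baseline + rng.poisson(np.maximum(frame - sc.baseline, 0.0)).astype(float)
        if sc.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, sc.read_noise_sd, frame.shape)
        exp_frames[f] = frame

    blanks = []
    for b in range(sc.n_blank_positions):
        blank_frames = np.empty((n_frames, h, w))
        for f in range(n_frames):
            frame = sc.baseline + background.copy()
            if sc.shot_noise:
                frame = sc.baseline + rng.poisson(np.maximum(frame - sc.baseline, 0.0)).astype(float)
            if sc.read_noise_sd > 0:
                frame = frame + rng.normal(0.0, sc.read_noise_sd, frame.shape)
            blank_frames[f] = frame
        blanks.append(
            ImageStack(blank_frames, role="blank", frame_times=times, position_id=f"blank{b}")
        )
    experimental = ImageStack(exp_frames, role="experimental", frame_times=times, position_id="pos0")
    return RenderResult(experimental, blanks, masks)
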