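"""Per-cell track assembly and trajectory-level analyses.

A :class:`CellTrack` holds one followed lineage: when a cell divides, one of
the two sisters is followed, so the observed ROI area halves at each division
while the underlying biomass grows exponentially.  This module reconstructs
the division-free exponential ("cumulative" area, doubling the observed area
once per past division), fits growth rates on a log-linear scale, quantifies
photodamage as growth-rate decrease relative to unexposed cells, regresses
cell signal on background across exposure settings, and analyzes medium-switch
perturbation experiments (dye-based arrival detection and fold-change
response).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "CellTrack",
    "GrowthFitResult",
    "cumulative_area",
    "fit_growth_rate",
    "growth_defect",
    "signal_background_ratio",
    "detect_medium_arrival",
    "fold_change_response",
]


@dataclass
class CellTrack:
    """One followed cell lineage sampled at a uniform frame interval.

    Parameters
    ----------
    track_id
        Identifier, unique within an experiment; also the ROI label used in
        rendered masks (must be >= 1 when rendering).
    time_min
        Acquisition times in minutes, strictly increasing and uniformly
        spaced.
    area
        Observed ROI area per frame (pixels or um^2).
    intensity
        ROI fluorescence intensity per frame (AU).
    division_frames
        Frame indices at which a division was called.  By convention a
        division frame is the *last* frame of the ending division cycle.
    """

    track_id: int
    time_min: np.ndarray
    area: np.ndarray
    intensity: np.ndarray
    division_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.division_frames = np.asarray(self.division_frames, dtype=int)
        n = self.time_min.size
        if self.area.size != n or self.intensity.size != n:
            raise DataError("time, area and intensity must have equal length")
        if n >= 2:
            dt = np.diff(self.time_min)
            if np.any(dt <= 0):
                raise DataError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise DataError("times must be uniformly spaced")
        if self.division_frames.size:
            if np.any(np.diff(self.division_frames) <= 0):
                raise DataError("division_frames must be strictly increasing")
            if self.division_frames.min() < 0 or self.division_frames.max() >= n:
                raise DataError("division_frames outside track span")

    @property
    def n_frames(self) -> int:
        return self.time_min.size

    @property
    def frame_interval_min(self) -> float:
        if self.n_frames < 2:
            return float("nan")
        return float(self.time_min[1] - self.time_min[0])


@dataclass(frozen=True)
class GrowthFitResult:
    """Exponential growth fit over a time window."""

    rate_per_h: float
    window_h: tuple[float, float]
    n_points: int
    r_squared: float


def cumulative_area(track: CellTrack) -> np.ndarray:
    """Division-free area series: observed area times ``2**k``.

    ``k`` is the number of divisions strictly before each frame, so the halving
    at each division is undone and a cell growing exponentially yields an exact
    jump-free exponential.
    """
    frames = np.arange(track.n_frames)
    n_before = np.searchsorted(track.division_frames, frames, side="left")
    return track.area * np.exp2(n_before.astype(float))


def fit_growth_rate(
    track: CellTrack,
    window_h: tuple[float, float] = (4.0, 10.0),
    method: str = "log-linear",
) -> GrowthFitResult:
    """Fit an exponential to the cumulative area inside ``window_h`` (hours).

    The default is least squares on log(area) versus time, which is exact for
    noiseless exponentials and robust for multiplicative noise; ``method=
    "nonlinear"`` refines with a direct exponential fit.
    """
    t_h = track.time_min / 60.0
    sel = (t_h >= window_h[0]) & (t_h <= window_h[1])
    if int(sel.sum()) < 5:
        raise DataError(
            f"only {int(sel.sum())} frames inside window {window_h}; need >= 5"
        )
    areas = cumulative_area(track)[sel]
    if np.any(areas <= 0):
        raise DataError("non-positive areas in fit window")
    t = t_h[sel]
    log_a = np.log(areas)
    slope, intercept = np.polyfit(t, log_a, 1)
    if method == "nonlinear":
        popt, _ = curve_fit(
            lambda x, a, r: a * np.exp(r * x),
            t,
            areas,
            p0=(np.exp(intercept), slope),
            maxfev=10000,
        )
        slope = popt[1]
        resid = areas - popt[0] * np.exp(slope * t)
        ss_tot = np.sum((areas - areas.mean()) ** 2)
    elif method == "log-linear":
        resid = log_a - (slope * t + intercept)
        ss_tot = np.sum((log_a - log_a.mean()) ** 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / float(ss_tot)
    return GrowthFitResult(float(slope), window_h, int(sel.sum()), r2)


def growth_defect(
    exposed_rates: Sequence[float], unexposed_rates: Sequence[float]
) -> tuple[float, float, float]:
    """Growth-rate decrease of exposed cells relative to unexposed ones.

    Returns ``(GR0, dGR, dGR_sd)``: the mean unexposed rate, the mean of the
    per-cell decreases ``GR0 - rate`` and their standard deviation.  Averaging
    across replicate experiments is left to the caller.
    """
    exposed = np.asarray(exposed_rates, dtype=float)
    unexposed = np.asarray(unexposed_rates, dtype=float)
    if exposed.size == 0 or unexposed.size == 0:
        raise DataError("both rate lists must be non-empty")
    if min(exposed.size, unexposed.size) < 25:
        logger.warning(
            "fewer than 25 tracks per group (%d exposed, %d unexposed)",
            exposed.size,
            unexposed.size,
        )
    gr0 = float(unexposed.mean())
    decreases = gr0 - exposed
    sd = float(decreases.std(ddof=1)) if decreases.size > 1 else 0.0
    return gr0, float(decreases.mean()), sd


def signal_background_ratio(
    background: Sequence[float],
    signal: Sequence[float],
    labels: Sequence[float] | None = None,
    exclude: Sequence[float] = (9.0,),
    fit_intercept: bool = True,
) -> float:
    """Least-squares slope of cell signal versus background intensity.

    ``labels`` are per-point exposure energies; groups listed in ``exclude``
    (default: the 9 uJ group, where the signal is close to camera noise) are
    left out of the fit.  With ``fit_intercept=False`` the line is forced
    through the origin.
    """
    b = np.asarray(background, dtype=float)
    s = np.asarray(signal, dtype=float)
    if b.size != s.size:
        raise DataError("background and signal must have equal length")
    if labels is not None:
        lab = np.asarray(labels, dtype=float)
        keep = ~np.isin(lab, np.asarray(exclude, dtype=float))
        b, s = b[keep], s[keep]
    if b.size < 2:
        raise DataError("need >= 2 points after exclusion")
    if np.ptp(b) == 0:
        raise DataError("degenerate fit: background values have zero variance")
    if fit_intercept:
        slope, _ = np.polyfit(b, s, 1)
    else:
        slope = float(np.dot(b, s) / np.dot(b, b))
    return float(slope)


def detect_medium_arrival(
    dye: Sequence[float],
    direction: str = "descent",
    smooth_window: int = 3,
    plateau_frames: int | None = None,
) -> int:
    """First frame at which the smoothed dye trajectory crosses the midpoint.

    The pre- and post-switch plateau levels are estimated as medians of the
    first and last ``plateau_frames`` frames (default: 10% of the trace, at
    least 3).  The plateaus must be separated by more than 4x their pooled
    standard deviation, otherwise no switch is detectable.
    """
    y = np.asarray(dye, dtype=float)
    n = y.size
    if n < 6:
        raise DataError("dye trajectory too short")
    if direction not in ("descent", "ascent"):
        raise ValueError(f"direction must be 'descent' or 'ascent', got {direction!r}")
    smoothed = median_filter(y, size=smooth_window, mode="nearest")
    k = plateau_frames if plateau_frames is not None else max(3, n // 10)
    pre = float(np.median(smoothed[:k]))
    post = float(np.median(smoothed[-k:]))
    plateau_sd = max(float(np.std(smoothed[:k])), float(np.std(smoothed[-k:])))
    if abs(pre - post) <= 4.0 * plateau_sd or pre == post:
        raise DataError("no switch detected: plateaus not separable")
    if direction == "descent" and pre < post:
        raise DataError("no switch detected: trajectory ascends, not descends")
    if direction == "ascent" and pre > post:
        raise DataError("no switch detected: trajectory descends, not ascends")
    midpoint = 0.5 * (pre + post)
    if direction == "descent":
        crossed = np.nonzero(smoothed < midpoint)[0]
    else:
        crossed = np.nonzero(smoothed > midpoint)[0]
    if crossed.size == 0:
        raise DataError("no switch detected: no midpoint crossing")
    return int(crossed[0])


def fold_change_response(
    intensity: Sequence[float],
    arrival: int,
    horizon_min: float,
    frame_interval_min: float,
    baseline_frames: int = 3,
    stat: str = "last",
) -> float:
    """Intensity fold change at ``horizon_min`` after the arrival frame.

    The baseline is the median of the ``baseline_frames`` frames immediately
    before arrival.  The response is the intensity at the last frame within
    ``(arrival, arrival + horizon]`` (``stat="last"``), i.e. at the horizon
    end; ``stat="median"`` instead takes the median over the whole window.
    For decline experiments the same ratio (< 1) reports the drop.
    """
    y = np.asarray(intensity, dtype=float)
    if arrival < baseline_frames:
        raise DataError(
            f"need >= {baseline_frames} pre-arrival frames, arrival at {arrival}"
        )
    n_h = int(np.floor(horizon_min / frame_interval_min + 1e-9))
    end = arrival + n_h
    if n_h < 1 or end >= y.size:
        raise DataError("horizon window empty or beyond end of track")
    baseline = float(np.median(y[arrival - baseline_frames : arrival]))
    if baseline <= 0:
        raise DataError("non-positive pre-arrival baseline")
    window = y[arrival + 1 : end + 1]
    if stat == "last":
        response = float(window[-1])
    elif stat == "median":
        response = float(np.median(window))
    else:
        raise ValueError(f"unknown stat {stat!r}")
    return response / baseline
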