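"""Flat-field/background correction and ROI intensity quantification.

Raw fluorescence frames carry a constant CCD baseline (an electronic offset,
500 AU by default), uneven illumination and background emission from the
device.  Blank positions (fields without cells) acquired in the same round
estimate background + illumination; the corrected frame is

    corrected = (experimental - blank) / (blank - baseline) * mean(blank)

which removes the background additively and the illumination pattern
multiplicatively while restoring the overall intensity scale.  Corrected
values may be negative; they are only filtered later, at ROI quantification.

Two ROI intensity variants are provided: subtracting the mean of a
surrounding cell-free area from the ROI mean on raw frames, and — on
corrected frames — removing sub-noise pixels and fitting a normal
distribution to the survivors (background noise itself being estimated as
the median over frames of the 90th-percentile intensity of a large cell-free
region).  A zero-crossing interpolation against NADPH standard solutions
converts intensity differences to intracellular concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "CorrectionConfig",
    "NoiseEstimate",
    "DEFAULT_BACKGROUND_NOISE_AU",
    "NADPH_STANDARDS_MM",
    "average_blanks",
    "correct_image",
    "correct_stack",
    "estimate_background_noise",
    "roi_intensity_gaussfit",
    "roi_intensity_subtract",
    "calibration_concentration",
    "measure_stack",
]

#: Background-noise threshold (AU) used when estimation is skipped.
DEFAULT_BACKGROUND_NOISE_AU = 10.0

#: NADPH standard-solution concentrations (mM) used for calibration.
NADPH_STANDARDS_MM = (0.2, 0.3, 0.5, 0.75, 1.0)


@dataclass
class ImageStack:
    """Time-ordered 2-D frames with acquisition metadata.

    ``role`` is one of ``experimental``, ``blank`` or ``corrected``.  Raw
    (non-corrected) frames must be non-negative; corrected frames are
    unbounded below.
    """

    frames: np.ndarray
    role: str = "experimental"
    frame_times: np.ndarray | None = None
    position_id: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DataError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.role not in ("experimental", "blank", "corrected"):
            raise DataError(f"unknown stack role {self.role!r}")
        if self.role != "corrected" and np.any(self.frames < 0):
            raise DataError("raw frames must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class CorrectionConfig:
    """Flat-field correction parameters.

    ``blank_mean_uses_raw=True`` rescales by the raw blank mean, exactly as
    the correction formula is written; ``False`` uses the baseline-subtracted
    mean instead (the printed form rescales by an offset-inflated factor).
    """

    ccd_baseline: float = 500.0
    blank_mean_uses_raw: bool = True

    def __post_init__(self) -> None:
        if self.ccd_baseline < 0:
            raise DataError("ccd_baseline must be >= 0")


def average_blanks(blanks: Sequence[ImageStack | np.ndarray]) -> ImageStack:
    """Pixelwise mean across blank positions, per acquisition round."""
    if len(blanks) == 0:
        raise DataError("need at least one blank position")
    arrays = [b.frames if isinstance(b, ImageStack) else np.asarray(b) for b in blanks]
    shape = arrays[0].shape
    for a in arrays[1:]:
        if a.shape != shape:
            raise DataError(f"blank shape mismatch: {a.shape} vs {shape}")
    times = blanks[0].frame_times if isinstance(blanks[0], ImageStack) else None
    mean = np.mean(np.stack(arrays, axis=0), axis=0)
    return ImageStack(mean, role="blank", frame_times=times, position_id="blank_mean")


def correct_image(
    experimental: np.ndarray,
    blank: np.ndarray,
    cfg: CorrectionConfig | None = None,
) -> np.ndarray:
    """Flat-field correction of one frame.

    ``(experimental - blank) / (blank - baseline) * mean(blank)``, evaluated
    pixelwise.  Every blank pixel must exceed the baseline (otherwise the
    denominator is not positive); the output is float and may be negative.
    """
    cfg = cfg if cfg is not None else CorrectionConfig()
    exp = np.asarray(experimental, dtype=float)
    blk = np.asarray(blank, dtype=float)
    if exp.shape != blk.shape:
        raise DataError(f"shape mismatch: experimental {exp.shape} vs blank {blk.shape}")
    bad = blk <= cfg.ccd_baseline
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise DataError(
            f"blank pixel ({r}, {c}) = {blk[r, c]} is <= baseline {cfg.ccd_baseline}"
        )
    mean_blank = float(blk.mean()) if cfg.blank_mean_uses_raw else float(
        (blk - cfg.ccd_baseline).mean()
    )
    return (exp - blk) / (blk - cfg.ccd_baseline) * mean_blank


def correct_stack(
    experimental: ImageStack,
    blank: ImageStack | np.ndarray,
    cfg: CorrectionConfig | None = None,
) -> ImageStack:
    """Apply :func:`correct_image` frame by frame.

    ``blank`` may be a per-round stack (same number of frames) or a single
    2-D blank image applied to every frame.
    """
    blk = blank.frames if isinstance(blank, ImageStack) else np.asarray(blank)
    out = np.empty(experimental.frames.shape, dtype=float)
    for f in range(experimental.n_frames):
        frame_blank = blk[f] if blk.ndim == 3 else blk
        out[f] = correct_image(experimental.frames[f], frame_blank, cfg)
    return ImageStack(
        out,
        role="corrected",
        frame_times=experimental.frame_times,
        position_id=experimental.position_id,
    )


@dataclass(frozen=True)
class NoiseEstimate:
    """Background-noise estimate from a large cell-free region."""

    per_frame_p90: np.ndarray
    experiment_noise: float
    area_pixel_count: int


def _nearest_rank_p90(values: np.ndarray) -> float:
    """Smallest value >= 90% of the pixels (nearest-rank order statistic)."""
    n = values.size
    k = int(np.ceil(0.9 * n))
    return float(np.partition(values, k - 1)[k - 1])


def estimate_background_noise(
    stack: ImageStack | np.ndarray,
    region: np.ndarray,
    min_pixels: int = 5000,
    percentile: str = "nearest-rank",
) -> NoiseEstimate:
    """Per-frame 90th-percentile intensity of a cell-free region.

    The region (a boolean mask over one frame) must exceed ``min_pixels``
    pixels and contain no cells on any frame.  The per-frame value is the
    nearest-rank 90th percentile (an actually observed pixel value that is
    >= 90% of the region's pixels); ``percentile="interpolated"`` uses the
    linear-interpolation convention instead.  The experiment-level noise is
    the median of the per-frame values.
    """
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack)
    if frames.ndim == 2:
        frames = frames[None]
    region = np.asarray(region, dtype=bool)
    count = int(region.sum())
    if count <= min_pixels:
        raise DataError(f"cell-free region has {count} pixels; need > {min_pixels}")
    per_frame = np.empty(frames.shape[0])
    for f in range(frames.shape[0]):
        vals = frames[f][region]
        if percentile == "nearest-rank":
            per_frame[f] = _nearest_rank_p90(vals)
        elif percentile == "interpolated":
            per_frame[f] = float(np.percentile(vals, 90))
        else:
            raise ValueError(f"unknown percentile convention {percentile!r}")
    return NoiseEstimate(per_frame, float(np.median(per_frame)), count)


def _truncated_normal_mean(values: np.ndarray, lower: float) -> float:
    """MLE mean of a normal left-truncated at ``lower``."""
    mu0, sd0 = float(values.mean()), float(values.std(ddof=0)) or 1.0

    def nll(params):
        mu, log_sd = params
        sd = np.exp(log_sd)
        z = (values - mu) / sd
        log_tail = norm.logsf((lower - mu) / sd)
        return float(np.sum(0.5 * z**2 + log_sd) + values.size * log_tail)

    res = minimize(nll, x0=np.array([mu0, np.log(sd0)]), method="Nelder-Mead")
    return float(res.x[0])


def roi_intensity_gaussfit(
    frame: np.ndarray,
    roi: np.ndarray,
    noise: float = DEFAULT_BACKGROUND_NOISE_AU,
    min_pixels: int = 5,
    truncated: bool = False,
) -> float:
    """ROI intensity: normal fit to pixels at or above the noise threshold.

    Pixels below ``noise`` are removed; a normal distribution is fitted to
    the survivors by maximum likelihood and its mean returned (the plain MLE
    mean equals the survivor sample mean; ``truncated=True`` instead fits a
    normal left-truncated at the threshold, accounting for the censored
    tail).  Fewer than ``min_pixels`` survivors yields NaN with a logged
    warning.
    """
    frame = np.asarray(frame, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    values = frame[roi]
    if values.size == 0:
        raise DataError("empty ROI")
    survivors = values[values >= noise]
    if survivors.size < min_pixels:
        logger.warning(
            "ROI has %d pixels >= noise %.3g (need %d); returning NaN",
            survivors.size,
            noise,
            min_pixels,
        )
        return float("nan")
    if truncated and np.isfinite(noise):
        return _truncated_normal_mean(survivors, noise)
    return float(survivors.mean())


def roi_intensity_subtract(
    frame: np.ndarray, roi: np.ndarray, background_region: np.ndarray
) -> float:
    """ROI mean minus the mean of a surrounding cell-free area (raw frames)."""
    frame = np.asarray(frame, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    bg = np.asarray(background_region, dtype=bool)
    if not roi.any() or not bg.any():
        raise DataError("ROI and background region must both be non-empty")
    return float(frame[roi].mean() - frame[bg].mean())


def calibration_concentration(
    standards: Sequence[tuple[float, float]],
) -> float:
    """Intracellular concentration from NADPH standard-solution intensities.

    ``standards`` are ``(concentration_mM, delta_intensity_AU)`` pairs where
    delta is cell-minus-surrounding intensity measured with that standard in
    the channel.  The intracellular concentration is where delta crosses
    zero, found by linear interpolation between the bracketing standards.
    """
    if len(standards) < 2:
        raise DataError("need at least two standards")
    pairs = sorted((float(c), float(d)) for c, d in standards)
    concs = np.array([p[0] for p in pairs])
    deltas = np.array([p[1] for p in pairs])
    diffs = np.diff(deltas)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise DataError("delta intensity must be strictly monotone in concentration")
    exact = np.nonzero(deltas == 0)[0]
    if exact.size:
        return float(concs[exact[0]])
    sign_change = np.nonzero(np.sign(deltas[:-1]) != np.sign(deltas[1:]))[0]
    if sign_change.size == 0:
        raise DataError("no zero crossing: concentration outside standard range")
    i = int(sign_change[0])
    c0, c1 = concs[i], concs[i + 1]
    d0, d1 = deltas[i], deltas[i + 1]
    return float(c0 + (0.0 - d0) * (c1 - c0) / (d1 - d0))


def measure_stack(
    stack: ImageStack,
    masks: np.ndarray,
    noise: float = DEFAULT_BACKGROUND_NOISE_AU,
    mode: str = "gaussfit",
    background_region: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame, per-label ROI intensities of a stack.

    ``masks`` is an integer label stack (0 = background) aligned with the
    frames.  ``mode="gaussfit"`` applies the noise-filtered normal fit (for
    corrected stacks); ``mode="subtract"`` subtracts the mean of
    ``background_region`` (for raw stacks).  Returns a DataFrame with columns
    position_id, frame, label, intensity_au, n_pixels, n_filtered.
    """
    masks = np.asarray(masks)
    if masks.shape != stack.frames.shape:
        raise DataError("masks must match stack shape")
    rows = []
    for f in range(stack.n_frames):
        frame = stack.frames[f]
        mask = masks[f]
        for label in np.unique(mask):
            if label == 0:
                continue
            roi = mask == label
            n_pixels = int(roi.sum())
            if mode == "gaussfit":
                value = roi_intensity_gaussfit(frame, roi, noise=noise)
                n_filtered = n_pixels - int((frame[roi] >= noise).sum())
            elif mode == "subtract":
                if background_region is None:
                    raise DataError("subtract mode needs a background_region")
                value = roi_intensity_subtract(frame, roi, background_region)
                n_filtered = 0
            else:
                raise ValueError(f"unknown mode {mode!r}")
            rows.append(
                {
                    "position_id": stack.position_id,
                    "frame": f,
                    "label": int(label),
                    "intensity_au": value,
                    "n_pixels": n_pixels,
                    "n_filtered": n_filtered,
                }
            )
    return pd.DataFrame(rows)
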