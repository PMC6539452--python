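"""Concentration calibration, CNR and Rose-criterion detectability.

The reconstructed XFCT pixel value is proportional to the Gd concentration;
an ordinary least-squares line through per-insertion ROI means versus the
known concentrations calibrates the image (slope = image units per mg/mL)
and its r-square quantifies linearity.  Detectability is summarized by the
contrast-to-noise ratio CNR = (mean_target - mean_background) / SD_background
(background pooled over all background ROIs, sample SD) and the Rose
criterion: a feature is detectable when CNR > 4, so the detectability limit
is where the fitted CNR-versus-concentration line crosses that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .geometry import VoxelGrid

__all__ = [
    "RoiSet",
    "CalibrationFit",
    "roi_stats",
    "roi_pixels",
    "fit_calibration",
    "apply_calibration",
    "cnr",
    "detectability_limit",
]

ROSE_THRESHOLD = 4.0


@dataclass(frozen=True)
class RoiSet:
    """Circular sampling regions: one target ROI per insertion plus background.

    Centers and radii in world mm on the reconstruction grid.
    """

    targets: tuple[tuple[tuple[float, float], float], ...]
    backgrounds: tuple[tuple[tuple[float, float], float], ...]

    def __post_init__(self) -> None:
        for (cx, cy), r in (*self.targets, *self.backgrounds):
            if r <= 0:
                raise ValueError("ROI radius must be positive")


@dataclass(frozen=True)
class CalibrationFit:
    """Least-squares line: image value = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_square: float
    residuals: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r_square <= 1.0 + 1e-9):
            raise ValueError("r_square must lie in [0, 1]")


def roi_pixels(image: np.ndarray, grid: VoxelGrid, center, radius) -> np.ndarray:
    """Values of voxels whose centers fall inside a disc ROI."""
    c = grid.voxel_centers()
    d2 = (c[:, 0] - center[0]) ** 2 + (c[:, 1] - center[1]) ** 2
    mask = d2 <= radius**2
    if not np.any(mask):
        raise ValueError("ROI contains no voxel centers")
    return image.ravel()[mask]


def roi_stats(image: np.ndarray, grid: VoxelGrid, center, radius) -> tuple[float, float, int]:
    """(mean, sample SD, n) over the voxels of one circular ROI."""
    vals = roi_pixels(image, grid, center, radius)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, int(vals.size)


def fit_calibration(means: Sequence[float], concentrations: Sequence[float]) -> CalibrationFit:
    """Ordinary least squares of ROI means against known concentrations."""
    y = np.asarray(means, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if y.size != c.size or y.size < 3:
        raise ValueError("need at least three (concentration, mean) points")
    if np.ptp(c) == 0:
        raise ValueError("degenerate design: all concentrations identical")
    res = stats.linregress(c, y)
    fitted = res.slope * c + res.intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_square=float(np.clip(r2, 0.0, 1.0)),
        residuals=tuple(y - fitted),
    )


def apply_calibration(image: np.ndarray, fit: CalibrationFit) -> np.ndarray:
    """Convert image units to mg/mL: (value - intercept) / slope.

    Negative calibrated values are preserved (clamping, if wanted, is a
    display choice).
    """
    if fit.slope <= 0:
        raise ValueError("calibration requires a positive slope")
    return (image - fit.intercept) / fit.slope


def cnr(
    image: np.ndarray,
    grid: VoxelGrid,
    target_roi,
    background_rois,
) -> float:
    """Contrast-to-noise ratio of one target ROI against pooled background.

    (mean_target - mean_background) / SD_background with the background
    pixels pooled over all background ROIs.  A zero background SD yields
    +/-inf (flagged distinguished value), 0/0 yields 0.
    """
    (t_center, t_radius) = target_roi
    t_mean, _, _ = roi_stats(image, grid, t_center, t_radius)
    pooled = np.concatenate(
        [roi_pixels(image, grid, c, r) for c, r in background_rois]
    )
    b_mean = float(pooled.mean())
    b_sd = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
    contrast = t_mean - b_mean
    if b_sd == 0.0:
        return 0.0 if contrast == 0.0 else float(np.sign(contrast)) * np.inf
    return contrast / b_sd


def detectability_limit(
    cnr_values: Sequence[float],
    concentrations: Sequence[float],
    threshold: float = ROSE_THRESHOLD,
) -> float:
    """Concentration where the fitted CNR(c) line crosses the Rose threshold.

    Fits CNR = a c + b by least squares over the finite points and returns
    (threshold - b) / a; a non-positive slope means no detectability
    crossing and raises.
    """
    v = np.asarray(cnr_values, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise ValueError("need at least two finite CNR values")
    res = stats.linregress(c[finite], v[finite])
    if res.slope <= 0:
        raise ValueError("non-positive CNR slope: no detectability crossing")
    return float((threshold - res.intercept) / res.slope)
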