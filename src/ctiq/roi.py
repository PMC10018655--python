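"""ROI statistics, contrast-to-noise ratio and line profiles.

CNR between two circular ROIs (by convention ROI1 = ascending aorta,
ROI2 = mediastinal fat):

    CNR = (HU_ROI1 - HU_ROI2) / sqrt(SD_ROI1^2 + SD_ROI2^2)

Reconstructions of the same patients are compared by the per-patient
difference CNR_recon1 - CNR_recon2 with a paired two-sided t-test.

Coordinates are centre-origin mm (see ``ctiq.stack``).  A pixel belongs to a
circular ROI iff its centre lies within diameter/2 of the ROI centre; ROI
SDs use the n-1 divisor.  Line profiles sample the image by bilinear
interpolation at a uniform step from one endpoint to the other, so the same
mm endpoints probe the same anatomy across reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .stack import mm_to_pixel_index, pixel_center_grid_mm

__all__ = [
    "ROISpec", "ROIStats", "CNRComparison", "LineProfile",
    "roi_stats", "cnr", "cnr_difference_analysis", "line_profile",
]


@dataclass(frozen=True)
class ROISpec:
    center: tuple              # (x, y) mm, centre-origin
    diameter: float = 15.0     # mm
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")


@dataclass(frozen=True)
class ROIStats:
    mean_hu: float
    sd_hu: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("empty ROI")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be non-negative")


@dataclass
class CNRComparison:
    per_patient_diffs: np.ndarray
    mean_diff: float
    sem: float
    t_statistic: float
    p_value: float
    degenerate: bool = False   # zero variance of the differences


@dataclass
class LineProfile:
    endpoints: tuple           # ((x0, y0), (x1, y1)) mm
    sample_step: float         # mm
    positions: np.ndarray      # mm along the line, ascending from 0
    values: np.ndarray         # HU


def roi_stats(slice_image: np.ndarray, spec: ROISpec, pixel_spacing: float) -> ROIStats:
    """Mean/SD over pixels whose centres fall inside the circular ROI."""
    slice_image = np.asarray(slice_image, dtype=np.float64)
    n_rows, n_cols = slice_image.shape
    cx, cy = spec.center
    r = spec.diameter / 2.0
    half_w = n_cols * pixel_spacing / 2.0
    half_h = n_rows * pixel_spacing / 2.0
    if cx - r < -half_w or cx + r > half_w or cy - r < -half_h or cy + r > half_h:
        raise ValueError(f"ROI {spec} extends outside the image")
    y, x = pixel_center_grid_mm(n_rows, n_cols, pixel_spacing)
    mask = (x - cx) ** 2 + (y - cy) ** 2 <= r ** 2
    vals = slice_image[mask]
    if vals.size == 0:
        raise ValueError("ROI contains no pixel centres")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return ROIStats(mean_hu=float(vals.mean()), sd_hu=sd, n_pixels=int(vals.size))


def cnr(roi1: ROIStats, roi2: ROIStats) -> float:
    denom = np.hypot(roi1.sd_hu, roi2.sd_hu)
    if denom == 0:
        raise ValueError("both ROI SDs are zero: CNR undefined")
    return (roi1.mean_hu - roi2.mean_hu) / denom


def cnr_difference_analysis(cnr_a, cnr_b) -> CNRComparison:
    """Paired comparison of per-patient CNR values between two reconstructions.

    diffs = a - b per patient; reports the mean difference, its standard
    error and a paired two-sided t-test (df = n - 1).  Significance is
    conventionally read at p < 0.05.
    """
    a = np.asarray(cnr_a, dtype=np.float64)
    b = np.asarray(cnr_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1D and paired by patient")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 patients for paired inference")
    diffs = a - b
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    sem = sd / np.sqrt(n)
    if sd == 0:
        # all differences identical: t undefined unless the mean is zero too
        return CNRComparison(per_patient_diffs=diffs, mean_diff=mean, sem=0.0,
                             t_statistic=0.0 if mean == 0 else np.inf,
                             p_value=1.0 if mean == 0 else 0.0, degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return CNRComparison(per_patient_diffs=diffs, mean_diff=mean, sem=float(sem),
                         t_statistic=float(t), p_value=float(p))


def line_profile(slice_image: np.ndarray, p0: tuple, p1: tuple,
                 sample_step: float, pixel_spacing: float,
                 interpolation: str = "bilinear") -> LineProfile:
    """Sample HU values along the segment p0 -> p1 (centre-origin mm).

    Samples are uniformly spaced and include both endpoints; the actual step
    is the largest value <= ``sample_step`` that divides the segment length
    evenly.  ``interpolation`` is "bilinear" (default) or "nearest".
    """
    if sample_step <= 0:
        raise ValueError("sample_step must be positive")
    slice_image = np.asarray(slice_image, dtype=np.float64)
    n_rows, n_cols = slice_image.shape
    half_w = n_cols * pixel_spacing / 2.0
    half_h = n_rows * pixel_spacing / 2.0
    for p in (p0, p1):
        if not (-half_w <= p[0] <= half_w and -half_h <= p[1] <= half_h):
            raise ValueError(f"endpoint {p} outside the image")
    length = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    n_steps = max(1, int(np.ceil(length / sample_step - 1e-9)))
    positions = np.linspace(0.0, length, n_steps + 1)
    frac = positions / length if length > 0 else positions * 0.0
    xs = p0[0] + frac * (p1[0] - p0[0])
    ys = p0[1] + frac * (p1[1] - p0[1])
    rows, cols = mm_to_pixel_index(xs, ys, n_rows, n_cols, pixel_spacing)
    order = {"bilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError("interpolation must be 'bilinear' or 'nearest'")
    values = ndimage.map_coordinates(slice_image, np.vstack([rows, cols]),
                                     order=order, mode="nearest")
    return LineProfile(endpoints=(tuple(p0), tuple(p1)), sample_step=sample_step,
                       positions=positions, values=values)
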