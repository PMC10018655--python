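"""Two-dimensional and radially averaged power spectra of CT image stacks.

The estimator follows standard CT noise-power-spectrum practice, applied
here to images that still contain anatomy (hence "PS" rather than "NPS"):

1. tile the central ``central_size`` x ``central_size`` window of each slice
   with non-overlapping ``roi_size`` x ``roi_size`` ROIs (defaults 128 / 64,
   giving 4 ROIs per slice);
2. mirror each ROI into an even-symmetric 2N x 2N block to suppress the edge
   artefacts that periodic DFT boundaries create in correlated images;
3. subtract the block mean and compute
   PS = (pixel_spacing^2 / n_pixels) * |DFT|^2  [HU^2 mm^2];
4. average the 2D PS over all ROIs of all slices of an examination;
5. radially average onto 1D bins of one frequency-grid step, and summarise a
   patient cohort per bin with the relative standard error of the mean.

With this normalisation Parseval's identity holds exactly per block:
sum(PS) * freq_spacing^2 equals the block's pixel variance (mean removed,
n divisor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stack import ImageStack

__all__ = [
    "PS2D", "PSCurve1D",
    "extract_central_rois", "mirror_roi", "roi_power_spectrum",
    "examination_ps", "radial_average", "cohort_ps",
]


@dataclass
class PS2D:
    """2D power spectrum on a square frequency grid (fftshifted layout)."""

    values: np.ndarray          # HU^2 mm^2, shape (side, side), DC at the centre
    freq: np.ndarray            # mm^-1, 1D fftshifted axis of length side
    freq_spacing: float         # mm^-1 grid step = 1 / (side * pixel_spacing)
    n_rois_averaged: int = 1
    n_slices_averaged: int = 1

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("PS2D values must be a square 2D grid")
        if np.any(self.values < 0):
            raise ValueError("power spectrum values must be non-negative")

    def radial_freq(self) -> np.ndarray:
        return np.hypot(self.freq[:, None], self.freq[None, :])

    def integral(self) -> float:
        """sum(values) * freq_spacing^2 — equals the mean per-ROI pixel
        variance by Parseval's identity."""
        return float(self.values.sum() * self.freq_spacing ** 2)


@dataclass
class PSCurve1D:
    """Radially averaged power spectrum."""

    bin_freq: np.ndarray        # mm^-1, ascending mean |f| per bin
    ps: np.ndarray              # HU^2 mm^2
    relative_se: np.ndarray | None = None   # percent, only for cohort curves
    n_patients: int = 1

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_freq) <= 0):
            raise ValueError("bin_freq must be strictly ascending")
        if np.any(self.ps < 0):
            raise ValueError("ps must be non-negative")


def extract_central_rois(slice_image: np.ndarray, roi_size: int = 64,
                         central_size: int = 128) -> list:
    """Non-overlapping roi_size tiles of the centred central_size window."""
    slice_image = np.asarray(slice_image)
    n_rows, n_cols = slice_image.shape
    if n_rows < central_size or n_cols < central_size:
        raise ValueError("image smaller than the central analysis window")
    if central_size % roi_size != 0:
        raise ValueError("central_size must be divisible by roi_size")
    r0 = (n_rows - central_size) // 2
    c0 = (n_cols - central_size) // 2
    k = central_size // roi_size
    rois = []
    for i in range(k):
        for j in range(k):
            rois.append(slice_image[r0 + i * roi_size: r0 + (i + 1) * roi_size,
                                    c0 + j * roi_size: c0 + (j + 1) * roi_size])
    return rois


def mirror_roi(roi: np.ndarray) -> np.ndarray:
    """Reflect an N x N ROI about its right and bottom edges into an
    even-symmetric 2N x 2N block (invariant under left-right and up-down
    flips), so the periodic extension seen by the DFT has no edge jumps."""
    roi = np.asarray(roi)
    if roi.ndim != 2 or roi.shape[0] != roi.shape[1]:
        raise ValueError("ROI must be square")
    return np.block([[roi, roi[:, ::-1]],
                     [roi[::-1, :], roi[::-1, ::-1]]])


def roi_power_spectrum(block: np.ndarray, pixel_spacing: float) -> PS2D:
    """PS of one (already mirrored) block: mean-subtract, DFT, scale.

    PS = (pixel_spacing^2 / n_pixels) * |DFT(block - mean)|^2.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.size == 0:
        raise ValueError("empty block")
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    side = block.shape[0]
    if block.ndim != 2 or block.shape[1] != side:
        raise ValueError("block must be square")
    dft = np.fft.fft2(block - block.mean())
    values = (pixel_spacing ** 2 / block.size) * np.abs(dft) ** 2
    return PS2D(values=np.fft.fftshift(values),
                freq=np.fft.fftshift(np.fft.fftfreq(side, d=pixel_spacing)),
                freq_spacing=1.0 / (side * pixel_spacing))


def examination_ps(stack: ImageStack, roi_size: int = 64,
                   central_size: int = 128) -> PS2D:
    """Average the mirrored-ROI PS over every ROI of every slice."""
    if stack.n_slices == 0:
        raise ValueError("empty stack")
    total = None
    n_rois = 0
    for slice_img in stack.voxels:
        for roi in extract_central_rois(slice_img, roi_size, central_size):
            ps = roi_power_spectrum(mirror_roi(roi), stack.pixel_spacing)
            total = ps.values if total is None else total + ps.values
            n_rois += 1
    side = 2 * roi_size
    return PS2D(values=total / n_rois,
                freq=np.fft.fftshift(np.fft.fftfreq(side, d=stack.pixel_spacing)),
                freq_spacing=1.0 / (side * stack.pixel_spacing),
                n_rois_averaged=n_rois, n_slices_averaged=stack.n_slices)


def radial_average(ps2d: PS2D) -> PSCurve1D:
    """Average the 2D PS over annular bins of width freq_spacing.

    The sample at |f| = 0 (DC) is excluded; bin k collects samples with
    k * df <= |f| < (k + 1) * df; the bin abscissa is the mean |f| of the
    contributing samples; empty bins are dropped.
    """
    fr = ps2d.radial_freq()
    df = ps2d.freq_spacing
    keep = fr > 0
    idx = np.floor(fr[keep] / df + 1e-9).astype(int)
    vals = ps2d.values[keep]
    freqs = fr[keep]
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    fsums = np.bincount(idx, weights=freqs, minlength=n_bins)
    nonempty = counts > 0
    return PSCurve1D(bin_freq=fsums[nonempty] / counts[nonempty],
                     ps=sums[nonempty] / counts[nonempty])


def cohort_ps(curves: Sequence[PSCurve1D]) -> PSCurve1D:
    """Per-bin mean across patients with relative standard error (%).

    relative_se = 100 * (SD across patients / sqrt(n)) / mean, per bin.
    """
    if len(curves) < 2:
        raise ValueError("cohort summary needs at least 2 curves")
    ref = curves[0].bin_freq
    for c in curves[1:]:
        if len(c.bin_freq) != len(ref) or not np.allclose(c.bin_freq, ref):
            raise ValueError("curves must share identical frequency bins")
    mat = np.stack([c.ps for c in curves])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rse = np.where(mean > 0, 100.0 * (sd / np.sqrt(len(curves))) / mean, 0.0)
    return PSCurve1D(bin_freq=ref.copy(), ps=mean, relative_se=rse,
                     n_patients=len(curves))
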