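"""Core image container for multi-slice CT data.

All in-plane geometry in this package uses millimetre coordinates with the
origin at the image centre: the pixel at (row r, col c) has its centre at
``x = (c + 0.5) * pixel_spacing - L/2`` and ``y = (r + 0.5) * pixel_spacing - L/2``
where ``L = n_cols * pixel_spacing``.  ``y`` increases with the row index
(downwards on screen), matching radiological display conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "pixel_center_grid_mm", "mm_to_pixel_index"]


@dataclass
class ImageStack:
    """A stack of axial CT slices in Hounsfield units.

    Parameters
    ----------
    voxels
        Array of shape (n_slices, n_rows, n_cols), HU values.
    pixel_spacing
        In-plane pixel size in mm (isotropic).
    slice_thickness
        Reconstructed slice thickness in mm.
    labels
        Free-form identifiers (patient, protocol, reconstruction, ...).
    """

    voxels: np.ndarray
    pixel_spacing: float
    slice_thickness: float = 0.625
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D (slice, row, col)")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def copy(self) -> "ImageStack":
        return ImageStack(
            voxels=self.voxels.copy(),
            pixel_spacing=self.pixel_spacing,
            slice_thickness=self.slice_thickness,
            labels=dict(self.labels),
        )

    def with_labels(self, **labels) -> "ImageStack":
        out = self.copy()
        out.labels.update(labels)
        return out


def pixel_center_grid_mm(n_rows: int, n_cols: int, pixel_spacing: float):
    """Return (y, x) mm coordinates of all pixel centres, origin at image centre.

    ``y`` has shape (n_rows, 1) and ``x`` shape (1, n_cols) for broadcasting.
    """
    y = (np.arange(n_rows) + 0.5) * pixel_spacing - n_rows * pixel_spacing / 2.0
    x = (np.arange(n_cols) + 0.5) * pixel_spacing - n_cols * pixel_spacing / 2.0
    return y[:, None], x[None, :]


def mm_to_pixel_index(x_mm: float, y_mm: float, n_rows: int, n_cols: int,
                      pixel_spacing: float) -> tuple:
    """Convert centre-origin mm coordinates to fractional (row, col) indices."""
    col = (x_mm + n_cols * pixel_spacing / 2.0) / pixel_spacing - 0.5
    row = (y_mm + n_rows * pixel_spacing / 2.0) / pixel_spacing - 0.5
    return row, col
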