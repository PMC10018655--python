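"""Deterministic anthropomorphic-ish chest phantom generator.

The phantom is a noiseless HU map: an elliptical body of soft tissue on an
air background, with configurable inserts (aorta-like disk, mediastinal fat,
lung fields, small vessels).  It stands in for patient anatomy so that the
downstream power-spectrum, CNR and line-profile machinery can be exercised
with known ground truth.  Generation is fully deterministic: no random state
is involved, so two identical configs give bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .stack import ImageStack, pixel_center_grid_mm

__all__ = ["Structure", "PhantomConfig", "generate_phantom_stack", "default_chest_phantom"]

# HU values typical of contrast-enhanced chest CT structures
AORTA_HU = 45.0
FAT_HU = -100.0
LUNG_HU = -850.0
VESSEL_HU = 50.0
BODY_HU = 30.0
AIR_HU = -1000.0


@dataclass(frozen=True)
class Structure:
    """One phantom insert.

    shape: "disk" (size = diameter, mm) or "ellipse" (size = (2a, 2b) axes, mm).
    center: (x, y) mm relative to the image centre.
    hu: value painted inside the structure (overwrites what is below it;
    structures are painted in list order).
    """

    shape: str
    center: tuple
    size: object
    hu: float

    def half_axes(self) -> tuple:
        if self.shape == "disk":
            r = float(self.size) / 2.0
            return r, r
        if self.shape == "ellipse":
            a, b = self.size
            return float(a) / 2.0, float(b) / 2.0
        raise ValueError(f"unknown structure shape {self.shape!r}")


@dataclass
class PhantomConfig:
    image_size: int = 512
    pixel_spacing: float = 0.75
    n_slices: int = 20
    body_axes: tuple = (320.0, 220.0)  # full axes (mm) of the body ellipse
    body_hu: float = BODY_HU
    background_hu: float = AIR_HU
    structures: Sequence[Structure] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.image_size < 128:
            raise ValueError("image_size must be at least 128 pixels")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.n_slices < 1:
            raise ValueError("n_slices must be at least 1")
        half_x = self.body_axes[0] / 2.0
        half_y = self.body_axes[1] / 2.0
        fov = self.image_size * self.pixel_spacing / 2.0
        t = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
        for s in self.structures:
            ax, ay = s.half_axes()
            cx, cy = s.center
            if abs(cx) + ax > fov or abs(cy) + ay > fov:
                raise ValueError(f"structure {s} extends outside the image field of view")
            # structure boundary must lie inside the body ellipse
            bx = cx + ax * np.cos(t)
            by = cy + ay * np.sin(t)
            if np.any((bx / half_x) ** 2 + (by / half_y) ** 2 > 1.0 + 1e-9):
                raise ValueError(f"structure {s} extends outside the body ellipse")


def _paint_ellipse(img: np.ndarray, x: np.ndarray, y: np.ndarray,
                   cx: float, cy: float, ax: float, ay: float, hu: float) -> None:
    mask = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    img[mask] = hu


def generate_phantom_stack(config: PhantomConfig) -> ImageStack:
    """Rasterise the phantom into a noiseless HU stack.

    A pixel belongs to a structure iff its centre lies inside the structure
    boundary (centre-in-shape rule).  All slices share the same anatomy.
    """
    n = config.image_size
    y, x = pixel_center_grid_mm(n, n, config.pixel_spacing)
    slice_img = np.full((n, n), config.background_hu, dtype=np.float64)
    _paint_ellipse(slice_img, x, y, 0.0, 0.0,
                   config.body_axes[0] / 2.0, config.body_axes[1] / 2.0,
                   config.body_hu)
    for s in config.structures:
        ax, ay = s.half_axes()
        _paint_ellipse(slice_img, x, y, s.center[0], s.center[1], ax, ay, s.hu)
    voxels = np.broadcast_to(slice_img, (config.n_slices, n, n)).copy()
    return ImageStack(voxels=voxels, pixel_spacing=config.pixel_spacing,
                      labels={"source": "phantom"})


def default_chest_phantom(image_size: int = 512, pixel_spacing: float = 0.75,
                          n_slices: int = 20) -> PhantomConfig:
    """Chest-like phantom: two lung fields, ascending aorta, anterior
    mediastinal fat, and a handful of 1-4 mm vessels inside the lungs.

    The aorta / fat pair mimics the ROI placement used for CNR (aorta ~45 HU,
    mediastinal fat ~-100 HU); small vessels support line-profile probes.
    """
    structures = [
        Structure("ellipse", (-70.0, 0.0), (110.0, 160.0), LUNG_HU),   # right lung
        Structure("ellipse", (70.0, 0.0), (110.0, 160.0), LUNG_HU),    # left lung
        Structure("disk", (0.0, 10.0), 30.0, AORTA_HU),                # ascending aorta
        Structure("disk", (0.0, -30.0), 24.0, FAT_HU),                 # anterior mediastinal fat
        # small vessels (diameter mm) inside the lung fields
        Structure("disk", (-70.0, -40.0), 2.0, VESSEL_HU),
        Structure("disk", (-60.0, 30.0), 3.0, VESSEL_HU),
        Structure("disk", (75.0, -25.0), 1.5, VESSEL_HU),
        Structure("disk", (65.0, 45.0), 4.0, VESSEL_HU),
    ]
    return PhantomConfig(image_size=image_size, pixel_spacing=pixel_spacing,
                         n_slices=n_slices, structures=structures)
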