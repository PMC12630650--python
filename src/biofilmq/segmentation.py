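"""Intensity-threshold segmentation shared by the pH and FLBA pipelines.

Both pipelines rest on the same two primitives: a global intensity threshold
that separates stained structures (microbial cells, lectin-bound matrix)
from background, and a partition of the lectin signal into cell-associated
versus intercellular fractions.  "Associated with microbial cells" is
operationalised as overlap with the cell mask dilated by a configurable
disc radius (default 1 px); the radius is a named knob so its influence can
be tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk

__all__ = [
    "DEFAULT_PIXEL_SIZE_UM",
    "IntensityRaster",
    "Mask",
    "threshold_mask",
    "extracellular_mask",
    "partition_lectin",
]

#: Default pixel size in µm: a 512-pixel frame spanning 101.61 µm.
DEFAULT_PIXEL_SIZE_UM = 101.61 / 512


@dataclass
class IntensityRaster:
    """A single-channel intensity image with pixel geometry.

    Coordinates are 0-based, row-major.  Intensities stay in their acquired
    integer range until ratio computation.
    """

    values: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    channel: Literal["green", "red"] = "green"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 16:
            raise ValueError("raster must be 2-D with dimensions >= 16x16")
        if np.any(self.values < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size ** 2


@dataclass
class Mask:
    """Boolean segmentation mask congruent with its source raster."""

    values: np.ndarray
    provenance: Literal["cell", "lectin", "extracellular"]
    threshold_used: Optional[float] = None
    method: Optional[Literal["otsu", "fixed"]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.values.sum())

    def area_um2(self, pixel_size: float) -> float:
        return self.area_px * pixel_size ** 2


def threshold_mask(
    raster: IntensityRaster,
    method: Literal["otsu", "fixed"] = "otsu",
    fixed_value: Optional[float] = None,
    provenance: Literal["cell", "lectin", "extracellular"] = "cell",
) -> Mask:
    """Segment a raster by global intensity thresholding (pixels > threshold).

    Otsu's method is the deterministic automatic default; a fixed manual
    threshold mirrors interactive thresholding in conventional image-analysis
    software.  The threshold actually applied is recorded on the mask for
    reproducibility.
    """
    values = raster.values
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        thr = float(fixed_value)
    elif method == "otsu":
        if np.all(values == values.flat[0]):
            raise ValueError(
                "Otsu threshold undefined for a constant raster"
            )
        thr = float(threshold_otsu(np.asarray(values)))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return Mask(values=values > thr, provenance=provenance,
                threshold_used=thr, method=method)


def _dilate(mask: np.ndarray, radius_px: int) -> np.ndarray:
    if radius_px < 0:
        raise ValueError("dilation radius must be >= 0")
    if radius_px == 0:
        return mask
    return dilation(mask, footprint=disk(radius_px)).astype(bool)


def extracellular_mask(cell: Mask, dilation_radius_px: int = 1) -> Mask:
    """Complement of the (dilated) cell mask: the extracellular biofilm area.

    Dilation by a small disc removes the blurred rims of cells whose
    intensity sits just under the threshold but whose ratio signal is still
    cell-contaminated.
    """
    grown = _dilate(cell.values, dilation_radius_px)
    return Mask(values=~grown, provenance="extracellular",
                threshold_used=cell.threshold_used, method=cell.method)


def partition_lectin(
    lectin: Mask, cell: Mask, dilation_radius_px: int = 1
) -> tuple[Mask, Mask]:
    """Split lectin signal into cell-associated and intercellular parts.

    Returns ``(cell_associated, intercellular)``; the two are disjoint and
    their union is the lectin mask (an exact partition, asserted here).
    """
    if lectin.values.shape != cell.values.shape:
        raise ValueError("lectin and cell masks must be congruent")
    grown = _dilate(cell.values, dilation_radius_px)
    assoc = lectin.values & grown
    inter = lectin.values & ~grown
    assert int(assoc.sum()) + int(inter.sum()) == int(lectin.values.sum())
    return (
        Mask(values=assoc, provenance="lectin"),
        Mask(values=inter, provenance="lectin"),
    )
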