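"""Fluorescence lectin-binding analysis (FLBA) biovolume quantification.

Matrix glycoconjugates are stained with fluorescently labelled lectins
(fucose-binding AAL or galactose-binding MNA-G, green channel) and microbial
cells counterstained (red channel); each field of view is acquired as a
6-slice z-stack spanning the biofilm height, slice 1 adjacent to the
substratum.  Biovolumes are COMSTAT-style: segmented area per slice times
the interslice distance, summed over the bottom (slices 1-2), middle (3-4)
and top (5-6) layers and over the whole stack.  Intercellular lectin
biovolume excludes lectin signal overlapping the (dilated) cell mask.
Normalised biovolumes divide lectin by microbial biovolume, layer-matched by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .segmentation import (
    DEFAULT_PIXEL_SIZE_UM,
    IntensityRaster,
    threshold_mask,
    partition_lectin,
)

__all__ = [
    "LAYERS",
    "SegConfig",
    "ZStack",
    "BiovolumeReport",
    "layer_slices",
    "stack_biovolumes",
    "normalize",
    "thickness",
    "fov_variability",
]

LAYERS = ("bottom", "middle", "top")


@dataclass
class SegConfig:
    """Segmentation settings for biovolume extraction."""

    method: Literal["otsu", "fixed"] = "otsu"
    fixed_cell: Optional[float] = None
    fixed_lectin: Optional[float] = None
    dilation_radius_px: int = 1


@dataclass
class ZStack:
    """Ordered two-channel z-stack; slice 0 is substratum-adjacent.

    ``slices`` has shape (n_slices, 2, rows, cols) with channel 0 = lectin
    (green) and channel 1 = cells (red).  The study layout is 6 slices, but
    any n >= 2 is accepted (layers then split into three contiguous thirds).
    """

    slices: np.ndarray
    interslice_um: float = 2.0
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    lectin_name: str = "AAL"
    carrier_id: str = "carrier"
    patient_id: str = "patient"
    treatment: str = "NoARG"
    fov_id: str = "fov"

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 4 or self.slices.shape[1] != 2:
            raise ValueError("slices must have shape (n, 2, rows, cols)")
        if self.slices.shape[0] < 2:
            raise ValueError("a z-stack needs at least 2 slices")
        if self.interslice_um <= 0:
            raise ValueError("interslice_um must be positive")

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])


def layer_slices(n_slices: int) -> dict[str, list[int]]:
    """Assign slice indices (0-based) to bottom/middle/top layers.

    Six slices map to {0,1}, {2,3}, {4,5}; other counts split into three
    equal contiguous thirds (extension for non-standard stacks).
    """
    parts = np.array_split(np.arange(n_slices), 3)
    return {name: part.tolist() for name, part in zip(LAYERS, parts)}


def _component_dict(per_slice: np.ndarray, layers: dict[str, list[int]]) -> dict:
    comp = {name: float(per_slice[idx].sum()) for name, idx in layers.items()}
    comp["total"] = float(per_slice.sum())
    return comp


@dataclass
class BiovolumeReport:
    """Layer-stratified biovolumes (µm³) for one z-stack.

    Each component dict has keys bottom/middle/top/total; layers are
    additive (bottom + middle + top = total) and the intercellular and
    cell-associated lectin parts partition the lectin biovolume exactly.
    """

    microbial_um3: dict
    lectin_um3: dict
    intercellular_um3: dict
    cell_associated_um3: dict
    thresholds: list = field(default_factory=list)
    interslice_um: float = 2.0
    normalized_total_pct: Optional[dict] = None
    normalized_intercellular_pct: Optional[dict] = None

    def __post_init__(self) -> None:
        for comp in (self.microbial_um3, self.lectin_um3,
                     self.intercellular_um3, self.cell_associated_um3):
            assert abs(sum(comp[k] for k in LAYERS) - comp["total"]) < 1e-9
        for key in (*LAYERS, "total"):
            s = self.intercellular_um3[key] + self.cell_associated_um3[key]
            assert abs(s - self.lectin_um3[key]) < 1e-9


def stack_biovolumes(stack: ZStack, seg: SegConfig | None = None) -> BiovolumeReport:
    """Quantify microbial, lectin and intercellular biovolumes of a stack.

    Per slice, both channels are thresholded, the lectin mask partitioned
    into cell-associated and intercellular parts, and pixel counts converted
    to areas (pixel_size²) and volumes (area x interslice distance), then
    summed per layer and overall.
    """
    seg = seg or SegConfig()
    n = stack.n_slices
    layers = layer_slices(n)
    px_area = stack.pixel_size ** 2
    microbial = np.zeros(n)
    lectin = np.zeros(n)
    inter = np.zeros(n)
    assoc = np.zeros(n)
    thresholds = []
    for i in range(n):
        green = IntensityRaster(stack.slices[i, 0], stack.pixel_size, "green")
        red = IntensityRaster(stack.slices[i, 1], stack.pixel_size, "red")
        try:
            cell_mask = threshold_mask(red, seg.method, seg.fixed_cell, "cell")
        except ValueError as exc:
            raise ValueError(f"slice {i + 1}, red channel: {exc}") from exc
        try:
            lectin_mask = threshold_mask(green, seg.method, seg.fixed_lectin,
                                         "lectin")
        except ValueError as exc:
            raise ValueError(f"slice {i + 1}, green channel: {exc}") from exc
        assoc_mask, inter_mask = partition_lectin(
            lectin_mask, cell_mask, seg.dilation_radius_px
        )
        vol = px_area * stack.interslice_um
        microbial[i] = cell_mask.area_px * vol
        lectin[i] = lectin_mask.area_px * vol
        inter[i] = inter_mask.area_px * vol
        assoc[i] = assoc_mask.area_px * vol
        thresholds.append(
            {"slice": i + 1, "cell": cell_mask.threshold_used,
             "lectin": lectin_mask.threshold_used}
        )
    report = BiovolumeReport(
        microbial_um3=_component_dict(microbial, layers),
        lectin_um3=_component_dict(lectin, layers),
        intercellular_um3=_component_dict(inter, layers),
        cell_associated_um3=_component_dict(assoc, layers),
        thresholds=thresholds,
        interslice_um=stack.interslice_um,
    )
    return normalize(report)


def normalize(report: BiovolumeReport,
              denominator: Literal["layer", "total"] = "layer") -> BiovolumeReport:
    """Attach normalised lectin biovolumes as % of microbial biovolume.

    ``denominator="layer"`` (default) divides each layer's lectin biovolume
    by that layer's microbial biovolume; ``"total"`` uses the whole-stack
    microbial biovolume for every layer.  Undefined percentages (zero
    microbial denominator) are reported as NaN.
    """

    def pct(num: dict) -> dict:
        out = {}
        for key in (*LAYERS, "total"):
            denom = (report.microbial_um3[key] if denominator == "layer"
                     else report.microbial_um3["total"])
            out[key] = 100.0 * num[key] / denom if denom > 0 else float("nan")
        return out

    report.normalized_total_pct = pct(report.lectin_um3)
    report.normalized_intercellular_pct = pct(report.intercellular_um3)
    return report


def thickness(stack: ZStack, occupancy_threshold: float = 0.005,
              seg: SegConfig | None = None) -> float:
    """Biofilm thickness estimate in µm.

    Counts slices whose microbial (red channel) area fraction reaches
    ``occupancy_threshold`` (default 0.5%) and multiplies by the interslice
    distance — a pragmatic proxy for the occupied biofilm height.
    """
    seg = seg or SegConfig()
    occupied = 0
    for i in range(stack.n_slices):
        red = IntensityRaster(stack.slices[i, 1], stack.pixel_size, "red")
        try:
            mask = threshold_mask(red, seg.method, seg.fixed_cell, "cell")
            frac = mask.area_px / mask.values.size
        except ValueError:
            frac = 0.0  # constant (empty) slice: unoccupied
        if frac >= occupancy_threshold:
            occupied += 1
    return occupied * stack.interslice_um


def fov_variability(values: Sequence[float]) -> float:
    """Coefficient of variation (sample SD / mean) across FOVs.

    Quantifies within-biofilm heterogeneity of pH or biovolume.  Returns NaN
    when the mean is zero (CV undefined); requires at least two values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)
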