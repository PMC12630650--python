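"""Extracellular pH ratiometry from paired green/red confocal images.

Workflow per field of view (FOV): segment microbial cells by intensity
thresholding and remove them, compute the per-pixel green/red ratio on the
remaining extracellular pixels, convert each pixel to pH through the
calibration curve, and summarise as the FOV mean +/- SD.  Conversion happens
*before* averaging: the calibration curve is nonlinear, so averaging ratios
first would bias the mean (the two orders are deliberately not equivalent).

FOV summaries aggregate to biofilm means (9 laser-marked FOVs per biofilm),
biofilm means to per-patient treatment-side means, and the split-mouth
design yields one paired ΔpH = pH(ARG) - pH(NoARG) per patient and
timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Optional

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, ph_from_ratio
from .segmentation import (
    IntensityRaster,
    Mask,
    extracellular_mask,
    threshold_mask,
)

__all__ = [
    "RatioFOV",
    "PHMap",
    "FOVSummary",
    "PairedPH",
    "ratio_map",
    "fov_summary",
    "process_fov",
    "biofilm_ph",
    "paired_delta_ph",
]


@dataclass
class RatioFOV:
    """Paired green/red rasters for one laser-marked field of view."""

    green: IntensityRaster
    red: IntensityRaster
    fov_id: str = "fov"
    carrier_id: str = "carrier"
    timepoint_min: int = 10

    def __post_init__(self) -> None:
        if self.green.values.shape != self.red.values.shape:
            raise ValueError("green and red rasters must be congruent")
        if self.timepoint_min not in (10, 35):
            raise ValueError("timepoint_min must be 10 or 35")


class RatioGrid(NamedTuple):
    """Per-pixel ratio with validity flags; ``reportable`` is False when the
    extracellular mask is empty (FOV dropped, no exception)."""

    ratio: np.ndarray
    valid: np.ndarray
    reportable: bool


@dataclass
class PHMap:
    """Per-pixel extracellular pH for one FOV."""

    ph: np.ndarray
    valid: np.ndarray
    valid_fraction: float
    out_of_domain_fraction: float


@dataclass
class FOVSummary:
    """Mean +/- SD extracellular pH of one FOV."""

    mean_ph: float
    sd_ph: float
    n_pixels: int
    fov_id: str = "fov"
    carrier_id: str = "carrier"
    timepoint_min: int = 10
    out_of_domain_fraction: float = 0.0
    reportable: bool = True


@dataclass
class PairedPH:
    """Within-patient paired pH difference (split-mouth design)."""

    patient_id: str
    timepoint_min: int
    ph_arg: float
    ph_noarg: float
    delta_ph: float = field(init=False)

    def __post_init__(self) -> None:
        self.delta_ph = self.ph_arg - self.ph_noarg


def ratio_map(fov: RatioFOV, extracellular: Mask) -> RatioGrid:
    """Per-pixel green/red ratio restricted to extracellular pixels.

    Pixels outside the mask or with zero red signal are invalid.  An empty
    extracellular mask marks the whole FOV unreportable rather than raising,
    so batch processing continues.
    """
    if extracellular.values.shape != fov.green.values.shape:
        raise ValueError("mask must be congruent with the rasters")
    green = np.asarray(fov.green.values, dtype=float)
    red = np.asarray(fov.red.values, dtype=float)
    valid = extracellular.values & (red > 0)
    ratio = np.full(green.shape, np.nan)
    ratio[valid] = green[valid] / red[valid]
    reportable = bool(extracellular.values.any())
    return RatioGrid(ratio=ratio, valid=valid, reportable=reportable)


def fov_summary(
    ratios: RatioGrid,
    curve: CalibrationCurve,
    fov_id: str = "fov",
    carrier_id: str = "carrier",
    timepoint_min: int = 10,
) -> tuple[FOVSummary, PHMap]:
    """Convert a ratio grid pixelwise to pH and summarise the FOV.

    Each valid pixel is converted through the calibration curve; pixels whose
    pH falls outside the calibrated domain are excluded from the mean/SD (the
    calibration is unsupported there) and their fraction is reported.
    """
    res = ph_from_ratio(ratios.ratio, curve)
    usable = ratios.valid & ~res.invalid & ~res.out_of_domain
    n_converted = int((ratios.valid & ~res.invalid).sum())
    out_frac = (
        float(res.out_of_domain[ratios.valid].sum()) / n_converted
        if n_converted else 0.0
    )
    ph_map = PHMap(
        ph=res.ph,
        valid=usable,
        valid_fraction=float(usable.sum()) / usable.size,
        out_of_domain_fraction=out_frac,
    )
    n = int(usable.sum())
    if not ratios.reportable or n == 0:
        summary = FOVSummary(
            mean_ph=float("nan"), sd_ph=float("nan"), n_pixels=0,
            fov_id=fov_id, carrier_id=carrier_id,
            timepoint_min=timepoint_min,
            out_of_domain_fraction=out_frac, reportable=False,
        )
        return summary, ph_map
    vals = res.ph[usable]
    summary = FOVSummary(
        mean_ph=float(vals.mean()),
        sd_ph=float(vals.std(ddof=1)) if n > 1 else 0.0,
        n_pixels=n,
        fov_id=fov_id,
        carrier_id=carrier_id,
        timepoint_min=timepoint_min,
        out_of_domain_fraction=out_frac,
    )
    return summary, ph_map


def process_fov(
    fov: RatioFOV,
    curve: CalibrationCurve,
    cell_channel: Literal["sum", "green", "red"] = "sum",
    threshold_method: Literal["otsu", "fixed"] = "otsu",
    fixed_value: Optional[float] = None,
    dilation_radius_px: int = 1,
) -> tuple[FOVSummary, PHMap]:
    """Full single-FOV pipeline: segment cells, mask, ratio, convert, summarise.

    Microbial cells take up C-SNARF-4 and appear bright in both channels, so
    by default they are detected on the summed green+red image and removed
    (after dilation) before the extracellular ratio is computed.
    """
    if cell_channel == "sum":
        img = fov.green.values.astype(float) + fov.red.values.astype(float)
    elif cell_channel == "green":
        img = fov.green.values
    else:
        img = fov.red.values
    raster = IntensityRaster(values=img, pixel_size=fov.green.pixel_size,
                             channel="green")
    cells = threshold_mask(raster, method=threshold_method,
                           fixed_value=fixed_value, provenance="cell")
    extra = extracellular_mask(cells, dilation_radius_px)
    grid = ratio_map(fov, extra)
    return fov_summary(grid, curve, fov_id=fov.fov_id,
                       carrier_id=fov.carrier_id,
                       timepoint_min=fov.timepoint_min)


def biofilm_ph(fovs: Iterable[FOVSummary]) -> tuple[float, int]:
    """Unweighted mean of FOV mean pH over one biofilm (nominally 9 FOVs).

    Returns ``(mean_ph, n_fovs_used)``; unreportable FOVs are skipped.
    """
    means = [f.mean_ph for f in fovs if f.reportable]
    if not means:
        raise ValueError("no reportable FOV in biofilm")
    return float(np.mean(means)), len(means)


def paired_delta_ph(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-patient paired pH differences ΔpH = ARG - NoARG.

    Parameters
    ----------
    summaries : DataFrame
        Tidy FOV summaries with columns ``patient_id, treatment, carrier_id,
        timepoint_min, mean_ph`` (one row per reportable FOV).  ``treatment``
        is ``"ARG"`` or ``"NoARG"``.

    For each patient and timepoint, FOV means are averaged per biofilm
    (carrier), biofilm means per treatment side, and the within-patient
    difference taken.  Patients missing a side at a timepoint are excluded
    and listed in the ``excluded`` attribute of the returned frame.
    """
    required = {"patient_id", "treatment", "carrier_id", "timepoint_min",
                "mean_ph"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    biofilm_means = (
        summaries.groupby(
            ["patient_id", "treatment", "timepoint_min", "carrier_id"],
            sort=True,
        )["mean_ph"].mean().reset_index()
    )
    side_means = (
        biofilm_means.groupby(["patient_id", "treatment", "timepoint_min"])
        ["mean_ph"].mean().unstack("treatment")
    )
    rows, excluded = [], []
    for (patient, tp), row in side_means.iterrows():
        if "ARG" not in row or "NoARG" not in row or row.isna().any():
            excluded.append((patient, tp, "missing treatment side"))
            continue
        pair = PairedPH(patient_id=str(patient), timepoint_min=int(tp),
                        ph_arg=float(row["ARG"]), ph_noarg=float(row["NoARG"]))
        rows.append({
            "patient_id": pair.patient_id,
            "timepoint_min": pair.timepoint_min,
            "ph_arg": pair.ph_arg,
            "ph_noarg": pair.ph_noarg,
            "delta_ph": pair.delta_ph,
        })
    out = pd.DataFrame(rows, columns=["patient_id", "timepoint_min", "ph_arg",
                                      "ph_noarg", "delta_ph"])
    out.attrs["excluded"] = excluded
    return out
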