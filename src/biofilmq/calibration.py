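"""Ratio-to-pH calibration for C-SNARF-4 ratiometry.

C-SNARF-4 shifts its emission spectrum with pH, so the ratio r between the
green- and red-channel intensities encodes pH independently of local dye
concentration.  The calibration relation used throughout this package is the
four-parameter log-logistic curve

    r(pH) = d + a / (1 + pH^b / c)

whose algebraic inverse,

    pH(r) = (((a / (r - d)) - 1) * c) ** (1 / b),

converts measured fluorescence ratios back to pH.  The published constants
for the dye/microscope combination this package targets are stored in
:data:`PUBLISHED_CURVE`.  The curve is strictly decreasing: more acidic
biofilm regions show a *higher* green/red ratio.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CalibrationCurve",
    "CalibrationTable",
    "PhResult",
    "FitReport",
    "PUBLISHED_CURVE",
    "ph_from_ratio",
    "ratio_from_ph",
    "fit_calibration",
    "calibration_from_images",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Parameters of the ratio->pH calibration relation.

    Attributes
    ----------
    a : float
        Amplitude of the ratio response (ratio units); the ratio spans
        ``(d, d + a)`` over all pH.
    d : float
        Lower ratio asymptote (ratio units), approached at high pH.
    c : float
        Scale constant; ``c ** (1 / b)`` is the pH at the half-response
        ratio ``d + a / 2``.
    b : float
        Hill-type exponent controlling the steepness of the transition.
    domain_lo, domain_hi : float
        pH interval over which the calibration is supported (the buffer
        titration range).  Conversions outside it are flagged, not clamped.
    """

    a: float
    d: float
    c: float
    b: float
    domain_lo: float = 4.0
    domain_hi: float = 8.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.c > 0 and self.b > 0):
            raise ValueError("calibration requires a > 0, c > 0 and b > 0")
        if not self.domain_lo < self.domain_hi:
            raise ValueError("domain_lo must be below domain_hi")

    @property
    def midpoint_ph(self) -> float:
        """pH at which the ratio equals ``d + a / 2``."""
        return float(self.c ** (1.0 / self.b))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "a": self.a,
                    "d": self.d,
                    "c": self.c,
                    "b": self.b,
                    "domain": [self.domain_lo, self.domain_hi],
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            obj = json.load(fh)
        lo, hi = obj.get("domain", (4.0, 8.0))
        return cls(a=obj["a"], d=obj["d"], c=obj["c"], b=obj["b"],
                   domain_lo=lo, domain_hi=hi)


#: Calibration constants published for C-SNARF-4 on the reference confocal
#: setup (buffers titrated pH 4.0-8.0 in 0.2 steps, three FOVs per buffer).
PUBLISHED_CURVE = CalibrationCurve(
    a=2.249, d=0.171, c=136_911_185_393.0, b=14.53178,
    domain_lo=4.0, domain_hi=8.0,
)


@dataclass
class CalibrationTable:
    """Per-buffer summary of the calibration image series.

    One row per buffer pH with the mean and SD of the per-pixel green/red
    ratio pooled over all fields of view of that buffer.
    """

    ph: np.ndarray
    mean_ratio: np.ndarray
    sd_ratio: np.ndarray
    n_fov: np.ndarray

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.mean_ratio = np.asarray(self.mean_ratio, dtype=float)
        self.sd_ratio = np.asarray(self.sd_ratio, dtype=float)
        self.n_fov = np.asarray(self.n_fov, dtype=int)
        if len({len(self.ph), len(self.mean_ratio), len(self.sd_ratio),
                len(self.n_fov)}) != 1:
            raise ValueError("all columns must have equal length")
        if len(np.unique(self.ph)) != len(self.ph):
            raise ValueError("pH values must be unique")
        if np.any(np.diff(self.ph) <= 0):
            order = np.argsort(self.ph)
            self.ph = self.ph[order]
            self.mean_ratio = self.mean_ratio[order]
            self.sd_ratio = self.sd_ratio[order]
            self.n_fov = self.n_fov[order]
        if np.any(self.mean_ratio <= 0):
            raise ValueError("mean_ratio must be positive")
        if np.any(self.n_fov < 1):
            raise ValueError("n_fov must be >= 1")

    def __len__(self) -> int:
        return len(self.ph)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ph": self.ph, "mean_ratio": self.mean_ratio,
             "sd_ratio": self.sd_ratio, "n_fov": self.n_fov}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTable":
        df = pd.read_csv(path)
        return cls(df["ph"].to_numpy(), df["mean_ratio"].to_numpy(),
                   df["sd_ratio"].to_numpy(), df["n_fov"].to_numpy())


class PhResult(NamedTuple):
    """Outcome of a ratio->pH conversion.

    ``ph`` holds NaN wherever ``invalid`` is True (ratio at or below the
    pole ``d``, or beyond the upper asymptote so the root argument is
    negative).  ``out_of_domain`` marks finite pH values falling outside the
    calibrated pH interval; they are returned, not clamped, so callers can
    report the flagged fraction.
    """

    ph: np.ndarray
    invalid: np.ndarray
    out_of_domain: np.ndarray


def ph_from_ratio(r, curve: CalibrationCurve = PUBLISHED_CURVE) -> PhResult:
    """Convert green/red fluorescence ratios to pH.

    Vectorised over ``r``.  Never raises on bad ratios: pixels where the
    relation is undefined come back NaN with ``invalid`` set, so raster
    application never aborts mid-image.
    """
    r = np.asarray(r, dtype=float)
    shifted = r - curve.d
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (curve.a / shifted - 1.0) * curve.c
    valid = (shifted > 0) & (arg >= 0) & np.isfinite(arg)
    ph = np.full(r.shape, np.nan)
    ph[valid] = arg[valid] ** (1.0 / curve.b)
    out_of_domain = valid & ((ph < curve.domain_lo) | (ph > curve.domain_hi))
    return PhResult(ph=ph, invalid=~valid, out_of_domain=out_of_domain)


def ratio_from_ph(x, curve: CalibrationCurve = PUBLISHED_CURVE):
    """Forward calibration relation r = d + a / (1 + pH^b / c).

    Strictly decreasing in pH; the exact algebraic inverse of
    :func:`ph_from_ratio`.  Raises for non-positive pH, where the power law
    is undefined.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("pH must be positive")
    out = curve.d + curve.a / (1.0 + x ** curve.b / curve.c)
    return out if out.ndim else float(out)


@dataclass
class FitReport:
    """Fitted curve plus residual diagnostics."""

    curve: CalibrationCurve
    residuals: np.ndarray
    rss: float
    warnings: list = field(default_factory=list)


def _default_init(table: CalibrationTable) -> CalibrationCurve:
    # deterministic initialisation: offset at the observed ratio floor,
    # amplitude as the observed range, midpoint at the centre of the grid
    d0 = float(table.mean_ratio.min())
    a0 = float(table.mean_ratio.max() - table.mean_ratio.min())
    b0 = 10.0
    mid = float(0.5 * (table.ph.min() + table.ph.max()))
    return CalibrationCurve(a=max(a0, 1e-6), d=d0, c=mid ** b0, b=b0,
                            domain_lo=float(table.ph.min()),
                            domain_hi=float(table.ph.max()))


def fit_calibration(table: CalibrationTable,
                    init: CalibrationCurve | None = None) -> FitReport:
    """Least-squares fit of the four-parameter curve to a calibration table.

    The fit is performed on (pH, mean_ratio) pairs in the parameterisation
    ``(a, d, b, log c)`` — ``c`` spans many orders of magnitude, so fitting
    its logarithm keeps the problem well conditioned.  Deterministic given
    the table and the initial curve (no random restarts).
    """
    if len(table) < 5:
        raise ValueError(
            "calibration fit needs >= 5 distinct pH levels "
            f"(got {len(table)}): 4 free parameters"
        )
    init = init or _default_init(table)
    x, y = table.ph, table.mean_ratio

    report_warnings: list[str] = []
    if np.any(np.diff(y) > 1e-3 * (y.max() - y.min())):
        report_warnings.append(
            "mean ratios are not monotonically decreasing in pH beyond "
            "tolerance; the fitted curve enforces monotonicity"
        )

    logx = np.log(x)

    def model(theta):
        a, d, b, logc = theta
        # r = d + a / (1 + exp(b*ln(pH) - ln(c)))
        return d + a / (1.0 + np.exp(b * logx - logc))

    def resid(theta):
        return model(theta) - y

    theta0 = np.array([init.a, init.d, init.b, math.log(init.c)])
    sol = least_squares(resid, theta0, method="lm", xtol=1e-15, ftol=1e-15,
                        gtol=1e-15, max_nfev=20000)
    a, d, b, logc = sol.x
    if a <= 0 or b <= 0:
        raise RuntimeError("calibration fit converged to a non-monotone curve")
    curve = CalibrationCurve(a=float(a), d=float(d), c=float(math.exp(logc)),
                             b=float(b), domain_lo=float(x.min()),
                             domain_hi=float(x.max()))
    res = sol.fun
    return FitReport(curve=curve, residuals=res, rss=float(res @ res),
                     warnings=report_warnings)


def calibration_from_images(
    fovs_by_ph: dict[float, Sequence],
    max_excluded_fraction: float = 0.5,
) -> CalibrationTable:
    """Build a calibration table from buffer image sets.

    Parameters
    ----------
    fovs_by_ph : dict
        Maps each buffer pH to a sequence of fields of view; each FOV is a
        ``(green, red)`` pair of 2-D intensity arrays (or objects exposing
        ``.green.values`` / ``.red.values``).  Buffers are cell-free, so no
        segmentation mask is applied — every pixel with nonzero red signal
        contributes.

    Zero-valued red pixels are excluded from the ratio; if more than
    ``max_excluded_fraction`` of the pixels of a buffer are excluded, the
    buffer is considered unusable and an error is raised.
    """
    if not fovs_by_ph:
        raise ValueError("no calibration images supplied")
    rows = {"ph": [], "mean_ratio": [], "sd_ratio": [], "n_fov": []}
    for ph_level in sorted(fovs_by_ph):
        fovs = fovs_by_ph[ph_level]
        if len(fovs) == 0:
            raise ValueError(f"buffer pH {ph_level}: no FOVs")
        ratios = []
        n_total = 0
        n_excluded = 0
        for fov in fovs:
            if hasattr(fov, "green"):
                green = np.asarray(getattr(fov.green, "values", fov.green), float)
                red = np.asarray(getattr(fov.red, "values", fov.red), float)
            else:
                green, red = (np.asarray(ch, float) for ch in fov)
            ok = red > 0
            n_total += red.size
            n_excluded += int(red.size - ok.sum())
            ratios.append(green[ok] / red[ok])
        if n_excluded > max_excluded_fraction * n_total:
            raise ValueError(
                f"buffer pH {ph_level}: {n_excluded}/{n_total} pixels have "
                "zero red signal; image set unusable"
            )
        pooled = np.concatenate(ratios)
        rows["ph"].append(ph_level)
        rows["mean_ratio"].append(float(pooled.mean()))
        rows["sd_ratio"].append(float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0)
        rows["n_fov"].append(len(fovs))
    return CalibrationTable(**rows)
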