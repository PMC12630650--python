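"""TIFF and manifest I/O plus pipeline orchestration.

Images travel as TIFF: a pH FOV is a 2-page stack (green, red) and an FLBA
FOV a (slices, 2, rows, cols) hyperstack, slice 1 substratum-adjacent.
Manifests are tidy CSVs mapping acquisition metadata to file paths.  All
results are written as long-format CSV (diff-able, no binary formats); every
result row carries the configuration hash and seed of the run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationCurve, CalibrationTable, fit_calibration
from .flba import LAYERS, SegConfig, ZStack, stack_biovolumes, thickness
from .ph import RatioFOV, paired_delta_ph, process_fov
from .segmentation import DEFAULT_PIXEL_SIZE_UM, IntensityRaster
from .stats import ASVTable, paired_differential_abundance

__all__ = [
    "read_image",
    "read_fov",
    "read_zstack",
    "write_fov",
    "write_zstack",
    "read_manifest",
    "run_pipeline",
]

MANIFEST_COLUMNS = {"patient_id", "treatment", "carrier_id", "fov_id", "path"}


def read_image(path) -> np.ndarray:
    """Read a single- or multi-page TIFF; errors name the offending file."""
    path = Path(path)
    try:
        return tifffile.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc


def read_fov(path, pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
             **meta) -> RatioFOV:
    """Load a two-page (green, red) TIFF as a :class:`RatioFOV`."""
    arr = read_image(path)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise IOError(
            f"{path}: expected a 2-page (green, red) TIFF, got shape {arr.shape}"
        )
    return RatioFOV(
        green=IntensityRaster(arr[0], pixel_size, "green"),
        red=IntensityRaster(arr[1], pixel_size, "red"),
        **meta,
    )


def read_zstack(path, interslice_um: float = 2.0,
                pixel_size: float = DEFAULT_PIXEL_SIZE_UM, **meta) -> ZStack:
    """Load a (slices, 2, rows, cols) TIFF hyperstack as a :class:`ZStack`."""
    arr = read_image(path)
    if arr.ndim != 4 or arr.shape[1] != 2:
        raise IOError(
            f"{path}: expected shape (slices, 2, rows, cols), got {arr.shape}"
        )
    return ZStack(slices=arr, interslice_um=interslice_um,
                  pixel_size=pixel_size, **meta)


def write_fov(path, green: np.ndarray, red: np.ndarray) -> None:
    arr = np.stack([green, red]).astype(np.float32)
    tifffile.imwrite(path, arr, photometric="minisblack")


def write_zstack(path, slices: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(slices, dtype=np.float32),
                     photometric="minisblack")


def read_manifest(path, extra_required=()) -> pd.DataFrame:
    """Read and validate a manifest CSV.

    Requires the core columns, ARG/NoARG treatment labels, and uniqueness of
    (carrier_id, fov_id[, timepoint_min]).
    """
    df = pd.read_csv(path)
    missing = (MANIFEST_COLUMNS | set(extra_required)) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    bad = set(df["treatment"].unique()) - {"ARG", "NoARG"}
    if bad:
        raise ValueError(f"manifest {path}: unknown treatment labels {bad}")
    keys = ["carrier_id", "fov_id"]
    if "timepoint_min" in df.columns:
        keys.append("timepoint_min")
    if df.duplicated(subset=keys).any():
        raise ValueError(f"manifest {path}: duplicate {tuple(keys)} rows")
    return df


def _config_hash(config: dict) -> str:
    # output location is not part of the analytic configuration
    payload = {k: v for k, v in config.items() if k not in ("out", "base_dir")}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_ph_stage(manifest: pd.DataFrame, curve: CalibrationCurve,
                 base_dir: Path | None = None, **fov_kwargs) -> pd.DataFrame:
    """Process every FOV of a pH manifest into tidy summary rows."""
    rows = []
    for _, rec in manifest.iterrows():
        path = Path(rec["path"])
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        fov = read_fov(
            path,
            fov_id=str(rec["fov_id"]), carrier_id=str(rec["carrier_id"]),
            timepoint_min=int(rec.get("timepoint_min", 10)),
        )
        summary, _ = process_fov(fov, curve, **fov_kwargs)
        rows.append({
            "patient_id": rec["patient_id"],
            "treatment": rec["treatment"],
            "carrier_id": rec["carrier_id"],
            "fov_id": rec["fov_id"],
            "timepoint_min": summary.timepoint_min,
            "mean_ph": summary.mean_ph,
            "sd_ph": summary.sd_ph,
            "n_pixels": summary.n_pixels,
            "out_of_domain_fraction": summary.out_of_domain_fraction,
            "reportable": summary.reportable,
        })
    return pd.DataFrame(rows)


def run_flba_stage(manifest: pd.DataFrame, seg: SegConfig | None = None,
                   base_dir: Path | None = None) -> pd.DataFrame:
    """Process every z-stack of an FLBA manifest into tidy biovolume rows."""
    seg = seg or SegConfig()
    rows = []
    for _, rec in manifest.iterrows():
        path = Path(rec["path"])
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        stack = read_zstack(
            path,
            interslice_um=float(rec.get("interslice_um", 2.0)),
            lectin_name=str(rec.get("lectin", "AAL")),
            patient_id=str(rec["patient_id"]),
            treatment=str(rec["treatment"]),
            carrier_id=str(rec["carrier_id"]), fov_id=str(rec["fov_id"]),
        )
        report = stack_biovolumes(stack, seg)
        thick = thickness(stack, seg=seg)
        for layer in (*LAYERS, "total"):
            rows.append({
                "patient_id": rec["patient_id"],
                "treatment": rec["treatment"],
                "lectin": rec.get("lectin", "AAL"),
                "carrier_id": rec["carrier_id"],
                "fov_id": rec["fov_id"],
                "layer": layer,
                "microbial_um3": report.microbial_um3[layer],
                "lectin_um3": report.lectin_um3[layer],
                "intercellular_um3": report.intercellular_um3[layer],
                "normalized_total_pct": report.normalized_total_pct[layer],
                "normalized_intercellular_pct":
                    report.normalized_intercellular_pct[layer],
                "thickness_um": thick,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: dict | str | Path, out_dir=None) -> dict:
    """Run the requested stages end-to-end from a JSON config.

    Config keys (all optional except ``out``): ``curve`` (JSON path) or
    ``calibration_table`` (CSV to fit), ``ph_manifest``, ``flba_manifest``,
    ``asv_table`` (CSV), ``seed``, ``out``.  Returns a dict of result paths;
    a stage failure raises with a machine-readable message naming the stage.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = json.load(fh)
    out = Path(out_dir or config["out"])
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(config)
    seed = config.get("seed", 0)
    produced: dict[str, str] = {}

    def _stamp(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["config_hash"] = chash
        df["seed"] = seed
        return df

    if "curve" in config:
        curve = CalibrationCurve.from_json(config["curve"])
    elif "calibration_table" in config:
        fit = fit_calibration(CalibrationTable.from_csv(config["calibration_table"]))
        curve = fit.curve
        curve.to_json(out / "curve.json")
        produced["curve"] = str(out / "curve.json")
    else:
        curve = None

    base_dir = Path(config.get("base_dir", "."))
    try:
        if "ph_manifest" in config:
            if curve is None:
                raise ValueError("pH stage requires a calibration curve")
            manifest = read_manifest(config["ph_manifest"],
                                     extra_required=("timepoint_min",))
            fov_df = run_ph_stage(manifest, curve, base_dir=base_dir)
            _stamp(fov_df).to_csv(out / "fov_summaries.csv", index=False)
            produced["fov_summaries"] = str(out / "fov_summaries.csv")
            paired = paired_delta_ph(fov_df[fov_df["reportable"]])
            _stamp(paired).to_csv(out / "paired_ph.csv", index=False)
            produced["paired_ph"] = str(out / "paired_ph.csv")
        if "flba_manifest" in config:
            manifest = read_manifest(config["flba_manifest"],
                                     extra_required=("lectin",))
            flba_df = run_flba_stage(manifest, base_dir=base_dir)
            _stamp(flba_df).to_csv(out / "biovolumes.csv", index=False)
            produced["biovolumes"] = str(out / "biovolumes.csv")
        if "asv_table" in config:
            table = ASVTable.from_frame(pd.read_csv(config["asv_table"]))
            res = paired_differential_abundance(table)
            _stamp(res.table).to_csv(out / "differential_abundance.csv",
                                     index=False)
            produced["differential_abundance"] = str(
                out / "differential_abundance.csv")
    except Exception as exc:
        report = {"error": type(exc).__name__, "message": str(exc),
                  "config_hash": chash}
        with open(out / "error.json", "w") as fh:
            json.dump(report, fh, indent=2)
        raise
    return produced
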