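"""Seeded synthetic-data generators with attached ground truth.

Every input the pipeline consumes can be generated here: calibration buffer
image sets, single-slice two-channel C-SNARF-4 fields of view, 6-slice FLBA
z-stacks, paired ASV count tables, and a full split-mouth cohort (10
patients, duplicate pH biofilms per side, 9 FOVs per biofilm, two sucrose
timepoints).  Generators return the emitted data *and* the truth used to
build it, so every pipeline stage can be tested against known answers
without any external download.

Defaults encode the study conditions: 512x512-pixel FOVs spanning
101.61 µm, imposed treatment effects ΔpH 0.19 (10 min) and 0.16 (35 min)
over placebo baselines 5.87/5.68, patient-dominant variance in the ASV
table, and a bottom-heavy lectin gradient halved by arginine treatment.

All randomness flows from one seed through named `numpy` SeedSequence
substreams, so identical spec + seed gives bit-identical output and partial
regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .calibration import CalibrationCurve, PUBLISHED_CURVE, ratio_from_ph
from .segmentation import DEFAULT_PIXEL_SIZE_UM, IntensityRaster, _dilate
from .ph import RatioFOV
from .flba import ZStack, layer_slices, LAYERS
from .stats import ASVTable

__all__ = [
    "NoiseModel",
    "NOISELESS",
    "constant_field",
    "two_region_field",
    "gradient_field",
    "reduced_cohort_spec",
    "AsvSpec",
    "FlbaSpec",
    "CohortSpec",
    "FOVTruth",
    "StackTruth",
    "gen_calibration_set",
    "gen_snarf_fov",
    "gen_flba_stack",
    "gen_asv_table",
    "gen_ph_cohort",
    "allocate_sides",
    "gen_cohort",
    "Cohort",
]


def _rng(seed_or_rng, *key: int) -> np.random.Generator:
    """Derive a named substream from a seed (or pass a Generator through)."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(np.random.SeedSequence(seed_or_rng, spawn_key=key))


@dataclass(frozen=True)
class NoiseModel:
    """Confocal noise approximation: Poisson shot noise + Gaussian read noise.

    ``poisson_gain`` is the photon count per intensity unit (0 disables shot
    noise); ``read_sd`` is the additive detector noise SD in intensity
    units.
    """

    poisson_gain: float = 1.0
    read_sd: float = 2.0

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(img, dtype=float)
        if self.poisson_gain > 0:
            out = rng.poisson(np.clip(out, 0, None) * self.poisson_gain)
            out = out / self.poisson_gain
        if self.read_sd > 0:
            out = out + rng.normal(0.0, self.read_sd, out.shape)
        return np.clip(out, 0.0, None)


NOISELESS = NoiseModel(poisson_gain=0.0, read_sd=0.0)


# ---------------------------------------------------------------------------
# calibration buffer sets

def gen_calibration_set(
    curve: CalibrationCurve = PUBLISHED_CURVE,
    noise_sd: float = 0.01,
    n_fov: int = 3,
    shape: tuple[int, int] = (64, 64),
    base_red: float = 120.0,
    seed=0,
) -> tuple[dict, pd.DataFrame]:
    """Buffer image series: 21 pH levels (4.0-8.0 in 0.2 steps) x n_fov FOVs.

    Each FOV is a cell-free (green, red) pair: red is constant at
    ``base_red`` and green = (true ratio + Gaussian(0, noise_sd)) * red per
    pixel.  Returns ``(fovs_by_ph, truth_table)`` where the truth table maps
    each level to its exact ratio.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    levels = np.round(np.arange(4.0, 8.0 + 1e-9, 0.2), 10)
    fovs_by_ph: dict[float, list] = {}
    truth = []
    for i, ph_level in enumerate(levels):
        true_ratio = float(ratio_from_ph(ph_level, curve))
        fovs = []
        for j in range(n_fov):
            rng = _rng(seed, 0, i, j)
            ratio = true_ratio + (
                rng.normal(0.0, noise_sd, shape) if noise_sd > 0 else 0.0
            )
            red = np.full(shape, base_red)
            green = ratio * red
            fovs.append((green, red))
        fovs_by_ph[float(ph_level)] = fovs
        truth.append({"ph": float(ph_level), "true_ratio": true_ratio})
    return fovs_by_ph, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# single-slice C-SNARF-4 FOVs

@dataclass
class FOVTruth:
    """Ground truth attached to a generated pH FOV."""

    ph_field: np.ndarray
    cell_mask: np.ndarray
    mean_extracellular_ph: float


def constant_field(value: float, shape: tuple[int, int]) -> np.ndarray:
    return np.full(shape, float(value))


def two_region_field(left: float, right: float,
                     shape: tuple[int, int]) -> np.ndarray:
    out = np.full(shape, float(left))
    out[:, shape[1] // 2:] = float(right)
    return out


def gradient_field(lo: float, hi: float, shape: tuple[int, int]) -> np.ndarray:
    col = np.linspace(lo, hi, shape[1])
    return np.tile(col, (shape[0], 1))


def _place_cells(shape, density, rng, min_axis=2, max_axis=6) -> np.ndarray:
    """Random-ellipse cell mask with approximately the requested coverage."""
    from skimage.draw import ellipse

    mask = np.zeros(shape, dtype=bool)
    if density <= 0:
        return mask
    target = density * mask.size
    attempts = 0
    while mask.sum() < target and attempts < 100_000:
        r0 = rng.uniform(0, shape[0])
        c0 = rng.uniform(0, shape[1])
        ra = rng.uniform(min_axis, max_axis)
        rb = rng.uniform(min_axis, max_axis)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(r0, c0, ra, rb, shape=shape, rotation=rot)
        mask[rr, cc] = True
        attempts += 1
    return mask


def gen_snarf_fov(
    ph_field,
    curve: CalibrationCurve = PUBLISHED_CURVE,
    shape: tuple[int, int] = (512, 512),
    cell_density: float = 0.15,
    noise: NoiseModel = NoiseModel(),
    base_red: float = 120.0,
    cell_intensity: float = 230.0,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    fov_id: str = "fov",
    carrier_id: str = "carrier",
    timepoint_min: int = 10,
    seed=0,
) -> tuple[RatioFOV, FOVTruth]:
    """Two-channel FOV whose extracellular ratio encodes a known pH field.

    The pH field (array or scalar) must lie inside the calibration domain.
    Microbial cells are random ellipses bright in *both* channels, so the
    thresholding route removes them; the extracellular green/red ratio
    equals ``ratio_from_ph(field)`` before noise.
    """
    if np.isscalar(ph_field):
        ph_field = constant_field(float(ph_field), shape)
    ph_field = np.asarray(ph_field, dtype=float)
    shape = ph_field.shape
    if np.any((ph_field < curve.domain_lo) | (ph_field > curve.domain_hi)):
        raise ValueError("pH field must lie within the calibration domain")
    if cell_density >= 1:
        raise ValueError("cell_density must leave extracellular pixels")

    cell_rng = _rng(seed, 1, 0)
    noise_rng = _rng(seed, 1, 1)
    cells = _place_cells(shape, cell_density, cell_rng)

    ratio = ratio_from_ph(ph_field, curve)
    red = np.full(shape, base_red)
    green = ratio * red
    green[cells] = cell_intensity
    red = red.copy()
    red[cells] = cell_intensity
    green = noise.apply(green, noise_rng)
    red = noise.apply(red, noise_rng)

    fov = RatioFOV(
        green=IntensityRaster(green, pixel_size, "green"),
        red=IntensityRaster(red, pixel_size, "red"),
        fov_id=fov_id, carrier_id=carrier_id, timepoint_min=timepoint_min,
    )
    truth = FOVTruth(
        ph_field=ph_field,
        cell_mask=cells,
        mean_extracellular_ph=float(ph_field[~cells].mean()),
    )
    return fov, truth


# ---------------------------------------------------------------------------
# FLBA z-stacks

@dataclass
class StackTruth:
    """Ground truth for a generated FLBA stack."""

    cell_masks: np.ndarray
    lectin_masks: np.ndarray
    microbial_um3: dict
    lectin_um3: dict
    intercellular_um3: dict
    thickness_um: float


def _smooth_field(shape, rng, sigma=4.0) -> np.ndarray:
    return gaussian_filter(rng.normal(size=shape), sigma)


def _top_k_mask(values: np.ndarray, k: int,
                allowed: Optional[np.ndarray] = None) -> np.ndarray:
    """Boolean mask of the k largest values (within ``allowed``)."""
    mask = np.zeros(values.shape, dtype=bool)
    if k <= 0:
        return mask
    if allowed is None:
        flat_idx = np.argpartition(values.ravel(), -k)[-k:]
        mask.ravel()[flat_idx] = True
    else:
        idx = np.flatnonzero(allowed.ravel())
        sub = values.ravel()[idx]
        top = idx[np.argpartition(sub, -k)[-k:]]
        mask.ravel()[top] = True
    return mask


def gen_flba_stack(
    microbial_fracs: Sequence[float],
    lectin_fracs: Sequence[float],
    overlap_fracs: Optional[Sequence[float]] = None,
    interslice_um: float = 2.0,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    noise: NoiseModel = NoiseModel(),
    background: float = 20.0,
    foreground: float = 200.0,
    dilation_radius_px: int = 1,
    occupancy_threshold: float = 0.005,
    seed=0,
    **stack_meta,
) -> tuple[ZStack, StackTruth]:
    """Blob-structured two-channel stack with exact requested area fractions.

    Per slice, cell and lectin masks are carved from smooth random fields by
    rank thresholding, so true pixel counts match the requested fractions to
    the nearest pixel.  ``overlap_fracs`` fixes the image-area fraction where
    lectin and cells overlap (default: half the feasible maximum); truth
    biovolumes, including the intercellular split under the stated dilation
    radius, are returned alongside.
    """
    m = np.asarray(microbial_fracs, dtype=float)
    l = np.asarray(lectin_fracs, dtype=float)
    if m.shape != l.shape:
        raise ValueError("per-slice fraction lists must have equal length")
    if np.any((m < 0) | (m > 1)) or np.any((l < 0) | (l > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    n = m.size
    if overlap_fracs is None:
        ov = 0.5 * np.minimum(m, l)
    else:
        ov = np.asarray(overlap_fracs, dtype=float)
    if np.any(ov > np.minimum(m, l) + 1e-12):
        raise ValueError("overlap fraction exceeds min(microbial, lectin)")

    npx = shape[0] * shape[1]
    slices = np.zeros((n, 2) + shape)
    cell_masks = np.zeros((n,) + shape, dtype=bool)
    lectin_masks = np.zeros((n,) + shape, dtype=bool)
    inter_px = np.zeros(n)
    for i in range(n):
        frng = _rng(seed, 2, i, 0)
        nrng = _rng(seed, 2, i, 1)
        n_cell = int(round(m[i] * npx))
        n_lect = int(round(l[i] * npx))
        n_ov = min(int(round(ov[i] * npx)), n_cell, n_lect)
        cell = _top_k_mask(_smooth_field(shape, frng), n_cell)
        lf = _smooth_field(shape, frng)
        lectin = _top_k_mask(lf, n_ov, allowed=cell)
        lectin |= _top_k_mask(lf, n_lect - n_ov, allowed=~cell)
        cell_masks[i] = cell
        lectin_masks[i] = lectin
        inter_px[i] = int((lectin & ~_dilate(cell, dilation_radius_px)).sum())
        green = background + (foreground - background) * lectin
        red = background + (foreground - background) * cell
        slices[i, 0] = noise.apply(green, nrng)
        slices[i, 1] = noise.apply(red, nrng)

    stack = ZStack(slices=slices, interslice_um=interslice_um,
                   pixel_size=pixel_size, **stack_meta)
    layers = layer_slices(n)
    vol = pixel_size ** 2 * interslice_um

    def comp(per_slice_px):
        d = {name: float(per_slice_px[idx].sum() * vol)
             for name, idx in layers.items()}
        d["total"] = float(per_slice_px.sum() * vol)
        return d

    cell_px = cell_masks.reshape(n, -1).sum(axis=1).astype(float)
    lect_px = lectin_masks.reshape(n, -1).sum(axis=1).astype(float)
    truth = StackTruth(
        cell_masks=cell_masks,
        lectin_masks=lectin_masks,
        microbial_um3=comp(cell_px),
        lectin_um3=comp(lect_px),
        intercellular_um3=comp(inter_px),
        thickness_um=float((cell_px / npx >= occupancy_threshold).sum()
                           * interslice_um),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# paired ASV tables

@dataclass(frozen=True)
class AsvSpec:
    """Paired ASV-table generator settings (patient-dominant variance)."""

    n_patients: int = 10
    n_asvs: int = 60
    depth: int = 20_000
    concentration: float = 0.5
    patient_sd: float = 2.0
    sample_sd: float = 0.1
    effect_asvs: tuple = ()
    effect_log: float = 0.0

    def __post_init__(self):
        if self.depth < 1000:
            raise ValueError("sequencing depth must be >= 1000")


def gen_asv_table(spec: AsvSpec = AsvSpec(), seed=0) -> tuple[ASVTable, dict]:
    """Paired 2 x n_patients ASV count table with known treatment shifts.

    Baseline log-abundances come from one Dirichlet draw; each patient adds
    a shared log-normal effect (identical on both mouth sides, making
    patient identity the dominant axis of variation); the ARG side adds
    ``effect_log`` (natural-log units) to the designated ASVs; counts are
    multinomial at the stated depth.

    ``effect_asvs`` indexes taxa by *baseline abundance rank* (0 = most
    abundant), so designated shifts land on community members that are
    actually observable at the stated depth.
    """
    base_rng = _rng(seed, 3, 0)
    base = np.log(base_rng.dirichlet(np.full(spec.n_asvs, spec.concentration))
                  + 1e-12)
    abundance_rank = np.argsort(-base)
    effect_idx = abundance_rank[list(spec.effect_asvs)]
    counts, patients, treatments = [], [], []
    for p in range(spec.n_patients):
        prng = _rng(seed, 3, 1, p)
        patient_effect = prng.normal(0.0, spec.patient_sd, spec.n_asvs)
        for trt in ("NoARG", "ARG"):
            logp = base + patient_effect
            if spec.sample_sd > 0:
                logp = logp + prng.normal(0.0, spec.sample_sd, spec.n_asvs)
            if trt == "ARG" and len(spec.effect_asvs):
                logp = logp.copy()
                logp[effect_idx] += spec.effect_log
            probs = np.exp(logp - logp.max())
            probs /= probs.sum()
            counts.append(prng.multinomial(spec.depth, probs))
            patients.append(f"P{p + 1:02d}")
            treatments.append(trt)
    table = ASVTable(
        counts=np.array(counts),
        patient_id=np.array(patients),
        treatment=np.array(treatments),
    )
    truth = {"effect_asvs": [int(j) for j in effect_idx],
             "effect_log": spec.effect_log,
             "shifted_taxa": [str(table.taxonomy[j]) for j in effect_idx]}
    return table, truth


# ---------------------------------------------------------------------------
# cohort layout

@dataclass(frozen=True)
class FlbaSpec:
    """FLBA arm of the cohort: one biofilm per lectin and side."""

    n_slices: int = 6
    interslice_um: float = 2.0
    shape: tuple = (256, 256)
    fovs_per_biofilm: int = 9
    lectins: tuple = ("AAL", "MNA-G")
    microbial_fracs: tuple = (0.30, 0.28, 0.24, 0.18, 0.10, 0.04)
    lectin_fracs_noarg: tuple = (0.12, 0.10, 0.07, 0.05, 0.03, 0.01)
    arg_lectin_scale: float = 0.5
    # biological scatter: log-normal factors on the lectin fractions, shared
    # across both mouth sides per patient / independent per FOV
    patient_lognorm_sd: float = 0.30
    fov_lognorm_sd: float = 0.15


@dataclass(frozen=True)
class CohortSpec:
    """Full split-mouth cohort layout and imposed effects.

    The default layout mirrors the study design: 10 patients, duplicate pH
    biofilms per treatment side imaged in 9 laser-marked FOVs at 10 and 35
    minutes of sucrose exposure, one FLBA biofilm per lectin and side, and
    one paired ASV sample per side.  ``true_delta_ph`` holds the imposed
    ARG - NoARG effect per timepoint over the placebo baselines ``base_ph``.
    """

    n_patients: int = 10
    biofilms_per_side_ph: int = 2
    fovs_per_biofilm: int = 9
    timepoints: tuple = (10, 35)
    base_ph: tuple = ((10, 5.87), (35, 5.68))
    true_delta_ph: tuple = ((10, 0.19), (35, 0.16))
    patient_sd: float = 0.30
    biofilm_sd: float = 0.05
    fov_sd: float = 0.12
    image_shape: tuple = (512, 512)
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    cell_density: float = 0.15
    noise: NoiseModel = NoiseModel()
    flba: FlbaSpec = field(default_factory=FlbaSpec)
    asv: AsvSpec = AsvSpec(effect_asvs=(0, 1, 2, 3, 4), effect_log=1.5)

    @property
    def base_ph_map(self) -> dict:
        return dict(self.base_ph)

    @property
    def delta_map(self) -> dict:
        return dict(self.true_delta_ph)


def allocate_sides(n_patients: int, seed=0) -> pd.DataFrame:
    """Split-mouth allocation by random permutation with block size 2.

    Within each consecutive block of two patients, one receives arginine on
    the left side and the other on the right, in random order — so blocks
    stay balanced.
    """
    rng = _rng(seed, 4, 0)
    sides = []
    for _ in range((n_patients + 1) // 2):
        block = ["left", "right"]
        rng.shuffle(block)
        sides.extend(block)
    return pd.DataFrame({
        "patient_id": [f"P{i + 1:02d}" for i in range(n_patients)],
        "arg_side": sides[:n_patients],
    })


def gen_ph_cohort(spec: CohortSpec = CohortSpec(), seed=0) -> pd.DataFrame:
    """Hierarchical FOV-level pH truth for the whole cohort (no rasters).

    Draws the nested random effects (patient, shared across sides; biofilm
    within side; FOV within biofilm) and returns one row per FOV and
    timepoint with the true mean extracellular pH.  This is the quantity the
    imaging pipeline estimates per FOV; rendering rasters on top of it only
    adds pixel-level noise.
    """
    alloc = allocate_sides(spec.n_patients, seed)
    rows = []
    for p in range(spec.n_patients):
        patient = f"P{p + 1:02d}"
        prng = _rng(seed, 5, p)
        patient_eff = prng.normal(0.0, spec.patient_sd)
        for treatment in ("ARG", "NoARG"):
            for bf in range(spec.biofilms_per_side_ph):
                carrier = f"{patient}-{treatment}-B{bf + 1}"
                biofilm_eff = prng.normal(0.0, spec.biofilm_sd)
                for fov in range(spec.fovs_per_biofilm):
                    fov_eff = prng.normal(0.0, spec.fov_sd)
                    for tp in spec.timepoints:
                        true_ph = (spec.base_ph_map[tp] + patient_eff
                                   + biofilm_eff + fov_eff)
                        if treatment == "ARG":
                            true_ph += spec.delta_map[tp]
                        rows.append({
                            "patient_id": patient,
                            "treatment": treatment,
                            "arg_side": alloc.loc[p, "arg_side"],
                            "carrier_id": carrier,
                            "fov_id": f"{carrier}-F{fov + 1}",
                            "timepoint_min": tp,
                            "true_ph": true_ph,
                            "mean_ph": true_ph,
                        })
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """In-memory synthetic cohort with ground truth."""

    spec: CohortSpec
    allocation: pd.DataFrame
    ph_fovs: pd.DataFrame
    asv_table: ASVTable
    asv_truth: dict
    flba_truth: pd.DataFrame
    flba_stacks: Optional[list] = None


def gen_cohort(spec: CohortSpec = CohortSpec(), seed=0,
               render_flba_stacks: bool = False) -> Cohort:
    """Generate the full cohort: pH truth table, ASV table, FLBA truths.

    FLBA stacks are summarised by their truth biovolumes per FOV; set
    ``render_flba_stacks=True`` to also keep the raster stacks (memory- and
    time-heavy for the full layout — intended for reduced specs).
    """
    alloc = allocate_sides(spec.n_patients, seed)
    ph_fovs = gen_ph_cohort(spec, seed)
    asv_table, asv_truth = gen_asv_table(spec.asv, seed)

    f = spec.flba
    flba_rows = []
    stacks = [] if render_flba_stacks else None
    for p in range(spec.n_patients):
        patient = f"P{p + 1:02d}"
        patient_factor = float(np.exp(
            _rng(seed, 6, p).normal(0.0, f.patient_lognorm_sd)))
        for treatment in ("ARG", "NoARG"):
            scale = f.arg_lectin_scale if treatment == "ARG" else 1.0
            for lectin in f.lectins:
                for fov in range(f.fovs_per_biofilm):
                    sub_key = (6, p, 0 if treatment == "ARG" else 1,
                               f.lectins.index(lectin), fov)
                    fov_factor = float(np.exp(
                        _rng(seed, *sub_key, 1).normal(0.0, f.fov_lognorm_sd)))
                    lectin_fracs = np.clip(
                        np.array(f.lectin_fracs_noarg) * scale
                        * patient_factor * fov_factor, 0.0, 0.95)
                    sub_seed = np.random.SeedSequence(
                        seed, spawn_key=sub_key
                    ).generate_state(1)[0] % (2 ** 31)
                    stack, truth = gen_flba_stack(
                        f.microbial_fracs, lectin_fracs,
                        interslice_um=f.interslice_um, shape=f.shape,
                        pixel_size=spec.pixel_size, noise=spec.noise,
                        seed=int(sub_seed),
                        lectin_name=lectin, patient_id=patient,
                        treatment=treatment,
                        carrier_id=f"{patient}-{treatment}-{lectin}",
                        fov_id=f"F{fov + 1}",
                    )
                    if stacks is not None:
                        stacks.append((stack, truth))
                    row = {"patient_id": patient, "treatment": treatment,
                           "lectin": lectin, "fov": fov + 1,
                           "thickness_um": truth.thickness_um}
                    for name in (*LAYERS, "total"):
                        row[f"microbial_{name}_um3"] = truth.microbial_um3[name]
                        row[f"lectin_{name}_um3"] = truth.lectin_um3[name]
                        row[f"intercellular_{name}_um3"] = (
                            truth.intercellular_um3[name])
                    flba_rows.append(row)
    return Cohort(
        spec=spec, allocation=alloc, ph_fovs=ph_fovs,
        asv_table=asv_table, asv_truth=asv_truth,
        flba_truth=pd.DataFrame(flba_rows), flba_stacks=stacks,
    )


def reduced_cohort_spec(**overrides) -> CohortSpec:
    """A desk-scale cohort spec for fast end-to-end runs.

    Shrinks image geometry and FOV counts while keeping the imposed effects
    and variance structure of the full design.
    """
    small = dict(
        image_shape=(128, 128),
        flba=FlbaSpec(shape=(96, 96), fovs_per_biofilm=2),
    )
    small.update(overrides)
    return replace(CohortSpec(), **small)
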