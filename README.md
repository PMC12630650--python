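# biofilmq

Quantitative image analysis and paired statistics for split-mouth dental
biofilm studies: microscale extracellular pH from ratiometric C-SNARF-4
confocal imaging, lectin-stained matrix biovolumes from 6-slice z-stacks,
and the downstream within-patient (arginine vs placebo) inference —
exercised end-to-end on seeded synthetic cohorts with known ground truth.

The package is aimed at researchers analysing in situ biofilm experiments
in which each participant carries treatment and control biofilms on
opposite sides of an intraoral splint (a split-mouth design), and every
outcome — pH, matrix biovolume, community composition — is therefore
paired within patients.

## What it computes

**pH ratiometry.** C-SNARF-4 shifts its emission with pH, so the ratio
*r* of green- to red-channel intensity encodes pH independently of dye
concentration. The calibration relation is a four-parameter log-logistic
curve, fitted to buffer titrations (pH 4.0–8.0 in 0.2 steps):

    r(pH) = d + a / (1 + pH^b / c)

with amplitude *a* = 2.249, offset *d* = 0.171, scale
*c* = 136 911 185 393 and exponent *b* = 14.53178 for the reference
dye/microscope combination, inverted analytically as

    pH(r) = (((a / (r − d)) − 1) · c)^(1/b).

Per field of view (FOV), microbial cells (bright in both channels) are
removed by intensity thresholding, the per-pixel extracellular ratio is
converted to pH *before* averaging (the curve is nonlinear, so the order
matters), and FOV means aggregate to biofilm (9 FOVs), patient-side and
paired ΔpH = pH(ARG) − pH(NoARG) summaries.

**FLBA biovolumes.** Fluorescently labelled lectins (fucose-binding AAL,
galactose-binding MNA-G) stain matrix glycoconjugates; cells are
counterstained. Each FOV is a 6-slice z-stack; biovolume is segmented area
per slice × interslice distance, reported for the bottom (slices 1–2),
middle (3–4) and top (5–6) layers and in total. Intercellular lectin
biovolume excludes lectin signal overlapping the dilated cell mask, and
normalised biovolumes divide lectin by microbial biovolume.

**Paired statistics.** Centred log-ratio (clr) transformed ASV counts are
compared patientwise with exact Wilcoxon signed-rank tests and
Benjamini–Hochberg correction; PCA on clr counts quantifies whether
samples group by patient or treatment; pH and biovolume comparisons use
linear mixed models with random intercepts for patient and
biofilm-within-patient (with a two-stage patient-mean aggregation as
cross-check); plus paired t-tests, simple OLS regressions and the paired
normal-approximation sample-size formula.

**Synthetic cohorts.** `biofilmq.synthetic` generates every input with
ground truth attached: calibration buffer images, single-slice pH FOVs,
FLBA stacks with exact requested area fractions, paired ASV tables with
patient-dominant variance, and the full 10-patient block-randomised
cohort. All randomness flows from one seed.

## Worked example

```python
import numpy as np
from biofilmq import PUBLISHED_CURVE, process_fov, paired_delta_ph
from biofilmq.stats import hierarchical_estimate
from biofilmq.synthetic import gen_snarf_fov, gen_ph_cohort

# one noisy 128x128 FOV at true pH 5.5 with 15% cell cover
fov, truth = gen_snarf_fov(5.5, shape=(128, 128), seed=2)
summary, ph_map = process_fov(fov, PUBLISHED_CURVE)
print(round(summary.mean_ph, 3))          # 5.474 (truth 5.5)

# a full cohort with imposed ΔpH 0.19 at 10 min
cohort = gen_ph_cohort(seed=5)
paired = paired_delta_ph(cohort)
print(round(paired.query("timepoint_min == 10").delta_ph.mean(), 3))  # 0.204

sub = cohort.query("timepoint_min == 10").rename(columns={
    "patient_id": "patient", "carrier_id": "biofilm",
    "treatment": "group", "mean_ph": "value"})
res = hierarchical_estimate(sub, reference="NoARG")
print(round(res.difference, 3))           # 0.204 (mixed model, p ~ 8e-18)
```

The numbers are what the code prints at those seeds: the single-FOV
estimate sits within the ±0.05 pH pixel-noise tolerance of its truth, and
the cohort-level mixed-model estimate recovers the imposed 0.19 treatment
effect to within the design's seed-to-seed scatter (SD ≈ 0.02).

The `analysis/` directory holds numbered narrative drivers
(`01_simulate_cohort.py` … `06_power_and_sample_size.py`) that run the
same computations at cohort scale and write tidy tables under `results/`.
A `biofilmq` CLI (`simulate`, `calibrate`, `ph`, `flba`, `stats`, `run`)
wraps the library for file-based workflows.

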