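# Methods

This note documents the models, conventions and numerical choices behind
`biofilmq`, and what the synthetic-data experiments do and do not show.

## Calibration model

The ratio–pH relation is parameterised in the monotone four-parameter
log-logistic form r(pH) = d + a/(1 + pH^b/c), and inverted analytically,
so the conversion pH(r) = (((a/(r−d)) − 1)·c)^(1/b) is its exact inverse
by construction. The stored reference constants are a = 2.249 (ratio
units; the ratio spans (d, d+a)), d = 0.171 (high-pH asymptote),
b = 14.53178 (steepness) and c = 136 911 185 393, whose b-th root,
c^(1/b) ≈ 5.84, is the half-response pH — comfortably inside the dye's
sensitive range. The curve is strictly decreasing: acidic regions show a
higher green/red ratio. The calibration domain is the buffer titration
range [4.0, 8.0].

Conversion never raises on bad pixels: ratios at or below the pole d, or
beyond the upper asymptote d + a (negative root argument), come back as
NaN with an `invalid` flag; finite pH values outside [4, 8] are returned
but flagged `out_of_domain` rather than clamped, and their fraction is
reported per FOV. Clamping would silently bias FOV means toward the
domain edges; exclusion-with-reporting keeps the bias visible.

Fitting uses deterministic least squares (Levenberg–Marquardt) in the
parameterisation (a, d, b, log c): c spans eleven orders of magnitude, so
fitting its logarithm keeps the Jacobian well conditioned. Initialisation
is data-driven and deterministic — d₀ = min ratio, a₀ = range, b₀ = 10,
c₀ = midpoint^b₀ — with no random restarts. A table needs at least five
distinct pH levels (four free parameters). On the 21 noiseless pairs
obtained by inverting the reference curve, the refit recovers all four
constants to ≈ 1e-15 relative error; with per-level ratio noise of
SD 0.01 the amplitude comes back within 0.05.

## Segmentation conventions

Global intensity thresholding (pixels strictly above the threshold) with
Otsu's method as the deterministic automatic default and a fixed manual
override; the threshold applied is recorded on every mask. Otsu on a
constant image has no defined threshold and raises (biovolume extraction
names the offending slice and channel).

"Associated with microbial cells" is operationalised as overlap with the
cell mask dilated by a disc of configurable radius, default 1 px (the
4-connected cross). The radius is a named knob in `SegConfig` because
adjacency is not otherwise defined; the partition of lectin signal into
cell-associated and intercellular parts is exact (disjoint union equal to
the lectin mask, asserted on every call). Coordinates are 0-based
row-major; masks carry no sub-pixel geometry. The default pixel size is
101.61/512 µm (a 512-pixel frame spanning 101.61 µm).

## pH pipeline

Per FOV: cells are detected on the summed green+red image (C-SNARF-4
accumulates in cells, so they are bright in both channels), removed after
dilation, the per-pixel green/red ratio computed on the remaining
extracellular pixels (zero-red pixels invalid), each pixel converted to
pH, and the mean ± SD taken over valid in-domain pixels. Conversion
precedes averaging deliberately: under the nonlinear curve, averaging
ratios first yields a different (biased) mean pH, and the two orders are
tested as not equivalent. Averaging is done in pH units, matching how
biofilm pH is conventionally reported; an [H+]-space mean can be computed
by the caller but is not the default.

FOV means aggregate unweighted to the biofilm mean (nominally 9 FOVs),
biofilm means to the treatment-side mean, and ΔpH = ARG − NoARG per
patient and timepoint. FOVs with no valid pixels are marked unreportable
and skipped; patients missing a side are excluded with a logged reason.

## FLBA biovolumes

Per slice and channel, thresholded area × pixel area × interslice
distance; summed over layers {1–2}, {3–4}, {5–6} for 6-slice stacks
(slice 1 substratum-adjacent) and over the whole stack. Stacks with other
slice counts split into three equal contiguous thirds. The interslice
distance is a required configuration value (default 2.0 µm) recorded in
every report; biovolumes are linear in it, so paired comparisons are
unaffected by the choice. Normalised biovolumes are percentages of the
microbial biovolume; the layer-matched denominator is the default, with
the whole-stack denominator available since either convention is
defensible. Thickness is estimated as (slices with microbial area
fraction ≥ 0.5%) × interslice distance — a pragmatic occupancy proxy, not
a surface reconstruction.

## Paired statistics

*clr transform*: log(count + pseudocount) centred by the sample mean log;
rows sum to zero. Pseudocount default 0.5 (configurable); zero is allowed
only for strictly positive counts.

*Differential abundance*: ASVs with mean relative abundance ≥ 1% over all
samples are tested (the filter precedes Benjamini–Hochberg, so it defines
the correction family — documented as affecting q). Patientwise clr
differences go into a two-sided Wilcoxon signed-rank test with the
classical drop-zeros convention; the null distribution of W⁺ is computed
exactly by dynamic programming over all 2ⁿ sign patterns for n ≤ 25
(untied ranks), with a tie-corrected, continuity-corrected normal
approximation otherwise. All-zero-difference ASVs report p = 1 with a
zero-variance flag. scipy's implementation is used only as an independent
cross-check in the test suite; a full 2¹⁰ enumeration oracle verifies the
exact p at n = 10. Log2 fold changes are computed on group mean relative
abundances, with the mean paired clr difference reported alongside, since
the fold-change denominator convention is otherwise ambiguous.

Because clr values are relative, boosting a subset of taxa necessarily
depresses the clr of all others; secondary detections with negative clr
effects on unshifted taxa are expected closure artefacts of compositional
analysis, and the analysis scripts label them as such.

*PCA*: centred PCA of the clr matrix; component signs fixed by making
each component's largest-magnitude loading positive, so scores are
reproducible across platforms.

*Hierarchical inference*: REML linear mixed model with a fixed group
effect and random intercepts for patient and biofilm-within-patient
(variance components). A two-stage aggregation (FOV → biofilm → patient
means, then a paired t-test) is always computed as a cross-check and used
as the estimate when the layout is degenerate (no replication below the
patient level), when the fit fails, or when the residual variance is
numerically zero — in that last case the patient-mean aggregation is
exact while the REML optimiser carries slop, so the model reduces exactly
to the paired t, as it should.

*Sample size*: the paired normal approximation
n = ⌈((z₁₋α/2 + z₁₋β)·σ/Δ)²⌉, with a one-sided variant as a named
convention. For the hydrogen-ion inputs Δ = 1.03×10⁻⁷ mol/L,
σ = 1.39×10⁻⁷ mol/L, α = 0.05, β = 0.20 this gives N = 15 (two-sided) or
N = 12 (one-sided). No standard one- or two-sample normal/t convention
reproduces a paired N as low as 7 from these inputs; the conventions are
therefore exposed as configuration and the discrepancy documented rather
than resolved.

## Synthetic cohorts

The generator defaults encode the study conditions: 10 patients with the
arginine side allocated by random permutation in blocks of 2; duplicate
pH biofilms per side, 9 FOVs per biofilm, timepoints 10 and 35 min;
placebo baseline pH 5.87 (10 min) and 5.68 (35 min) with imposed
treatment effects ΔpH +0.19 and +0.16; one FLBA biofilm per lectin (AAL,
MNA-G) and side; one paired ASV sample per side at depth 20 000.

Variance components for pH are patient SD 0.30 (shared across sides —
the split-mouth design cancels it in ΔpH), biofilm SD 0.05 and FOV SD
0.12. The patient SD matches the between-subject spread of biofilm pH;
duplicate biofilms grown side by side on one splint are taken to be
substantially more repeatable than the cross-patient spread, while
FOV-to-FOV scatter dominates within a biofilm, reflecting how strongly
local biofilm architecture shapes pH microenvironments. Under these
components the design standard error of the cohort-mean ΔpH is
√(2·(0.05²/2 + 0.12²/18)/10) ≈ 0.02, so a 10-patient cohort estimates
the imposed effect to ±0.05 in ~99% of seeds.

Images: the extracellular ratio field encodes the pH field exactly
through the forward curve (red constant at 120, green = ratio × red);
cells are random ellipses bright (230) in both channels so the
thresholding route removes them; noise is Poisson shot noise on
intensities plus additive Gaussian read noise (SD 2), the standard
confocal approximation. On noiseless images the pipeline recovers the pH
field to ≤ 1e-9 per pixel. Under the default noise, per-FOV estimates
carry a small acid-ward bias (~0.03 pH at 128 px) from the convexity of
the conversion under ratio noise; it is common to both treatment sides
and cancels in ΔpH.

FLBA stacks are carved from smoothed random fields by rank thresholding,
so true per-slice areas match the requested fractions to the nearest
pixel; the default lectin gradient is bottom-heavy
(0.12 … 0.01 area fraction) with the microbial gradient
(0.30 … 0.04) spanning all six slices, and the arginine side scales
lectin production by 0.5. Log-normal biological scatter (patient-level
SD 0.30 shared across sides, FOV-level SD 0.15) keeps paired t statistics
in a realistic range. The ASV generator draws a skewed baseline from a
Dirichlet(0.5), adds a patient effect (log SD 2.0) shared by both sides,
and shifts designated taxa — indexed by baseline abundance rank so the
shifts land on observable community members — by +1.5 natural-log units
on the arginine side.

All randomness descends from a single seed through named SeedSequence
substreams (per patient, FOV, slice), so identical spec + seed is
bit-identical and partial regeneration is stable.

### What the synthetic experiments do not show

The generators emulate the *structure* of the data, not its biology:
constant-pH fields per FOV (no microcolony pH gradients), geometric cell
shapes, no optical PSF or depth attenuation, no arginine metabolism or
community ecology, and multinomial (not overdispersed per-taxon)
sequencing noise. Passing tests demonstrate that the pipeline recovers
known inputs under the stated noise model — not that the segmentation or
calibration would be unbiased on real confocal data.

## Problem sizes

The test suite and analysis drivers run at desk scale as the package's
own choice of problem size: images 64–128 px (full 512-px geometry is
exercised by the generator defaults and available via
`CohortSpec()`/`--full`), FLBA stacks 48–96 px, 100-seed recovery suites
on the FOV-summary fast path (`gen_ph_cohort`, which draws the same
hierarchical truth the imaging pipeline estimates; raster-level agreement
is checked separately at small scale), and 10 000-rep null simulations at
30 ASVs × depth 2 000. The methods and conclusions are scale-free; the
acceptance checks state their tolerances explicitly.
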