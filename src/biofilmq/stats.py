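"""Paired downstream statistics for the split-mouth design.

Covers the compositional differential-abundance route (centred log-ratio
transform, patientwise paired Wilcoxon signed-rank tests with
Benjamini-Hochberg correction), PCA on clr counts, hierarchical pH/biovolume
inference (random intercepts for patient and biofilm-within-patient),
classical paired t-tests and simple regressions, and the paired
sample-size computation.

The Wilcoxon signed-rank null distribution is computed exactly here (all
2^n sign assignments via dynamic programming, zeros dropped) so that large
permutation/null simulation suites stay fast; scipy's implementation serves
as an independent cross-check in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ASVTable",
    "DiffAbundanceResult",
    "clr_transform",
    "wilcoxon_signed_rank",
    "paired_differential_abundance",
    "pca_clr",
    "HierarchicalResult",
    "hierarchical_estimate",
    "paired_t",
    "regress",
    "sample_size_paired",
]


# ---------------------------------------------------------------------------
# ASV container

@dataclass
class ASVTable:
    """Paired ASV count table: samples x ASVs with patient/treatment labels.

    For paired analyses every patient must contribute exactly one ARG and
    one NoARG sample.
    """

    counts: np.ndarray
    patient_id: np.ndarray
    treatment: np.ndarray
    taxonomy: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.patient_id = np.asarray(self.patient_id)
        self.treatment = np.asarray(self.treatment)
        if self.taxonomy is None:
            self.taxonomy = np.array(
                [f"ASV{i + 1}" for i in range(self.counts.shape[1])]
            )
        else:
            self.taxonomy = np.asarray(self.taxonomy)
        if len(self.patient_id) != self.counts.shape[0]:
            raise ValueError("one patient label per sample required")
        if not set(np.unique(self.treatment)) <= {"ARG", "NoARG"}:
            raise ValueError("treatment labels must be 'ARG' or 'NoARG'")

    @property
    def n_samples(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_asvs(self) -> int:
        return int(self.counts.shape[1])

    def check_paired(self) -> list:
        """Return sorted patient labels; raise naming any unpaired patient."""
        patients = np.unique(self.patient_id)
        for p in patients:
            sel = self.patient_id == p
            treatments = sorted(self.treatment[sel].tolist())
            if treatments != ["ARG", "NoARG"]:
                raise ValueError(
                    f"patient {p!r} is not a complete ARG/NoARG pair "
                    f"(has {treatments})"
                )
        return patients.tolist()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.taxonomy)
        df.insert(0, "patient_id", self.patient_id)
        df.insert(1, "treatment", self.treatment)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ASVTable":
        meta = ["patient_id", "treatment"]
        asv_cols = [c for c in df.columns if c not in meta]
        return cls(
            counts=df[asv_cols].to_numpy(),
            patient_id=df["patient_id"].to_numpy(),
            treatment=df["treatment"].to_numpy(),
            taxonomy=np.array(asv_cols),
        )


# ---------------------------------------------------------------------------
# clr transform

def clr_transform(counts, pseudocount: float = 0.5) -> np.ndarray:
    """Centred log-ratio transform, row-wise (samples x features).

    Each sample's counts are offset by ``pseudocount``, log-transformed, and
    centred by the sample's mean log — i.e. log of each part relative to the
    sample's geometric mean.  Rows therefore sum to zero.  ``pseudocount=0``
    is permitted only when every count is strictly positive.
    """
    if isinstance(counts, ASVTable):
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and np.any(counts == 0):
        raise ValueError("pseudocount 0 requires strictly positive counts")
    logs = np.log(counts + pseudocount)
    return logs - logs.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank

@lru_cache(maxsize=64)
def _signed_rank_null_cdf(n: int) -> np.ndarray:
    """Exact null distribution of W+ for n untied ranks.

    Dynamic programming over the polynomial prod_i (1 + x^i); entry k of the
    returned array is P(W+ <= k) under the 2^n equiprobable sign patterns.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for i in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[i:] = counts[:-i] if i else counts
        counts = counts + shifted
    pmf = counts / 2.0 ** n
    return np.cumsum(pmf)


def wilcoxon_signed_rank(
    differences: Sequence[float],
    exact_max_n: int = 25,
) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (the classical convention); |differences|
    are mid-ranked and W+ is the rank sum of the positive ones.  The p-value
    uses the exact 2^n null for n <= ``exact_max_n`` when ranks are untied,
    otherwise a normal approximation with tie correction and continuity
    correction.

    Returns ``(W+, p, n_used)``; n_used = 0 (all differences zero) yields
    p = 1 — a zero-variance, uninformative comparison.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    has_ties = len(np.unique(ranks)) != n
    if n <= exact_max_n and not has_ties:
        cdf = _signed_rank_null_cdf(n)
        w = int(round(w_pos))
        p_low = cdf[w]
        p_high = 1.0 - (cdf[w - 1] if w > 0 else 0.0)
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = n * (n + 1) / 4.0
        tie_adjust = sum(
            t ** 3 - t for t in np.unique(ranks, return_counts=True)[1]
        )
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_adjust / 48.0
        z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / math.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(1.0, p)
    return w_pos, float(p), n


# ---------------------------------------------------------------------------
# paired differential abundance

@dataclass
class DiffAbundanceResult:
    """Per-ASV paired differential-abundance results (tidy frame).

    ``table`` columns: asv, mean_rel_abundance_arg_pct,
    mean_rel_abundance_noarg_pct, clr_effect (mean paired clr difference,
    ARG - NoARG), log2_fold_change, wilcoxon_w, p, q, zero_variance.
    ``excluded_all_zero`` lists ASVs with no reads anywhere;
    ``below_abundance_filter`` lists ASVs present but under the relative-
    abundance cutoff (not tested, hence not part of the BH family).
    """

    table: pd.DataFrame
    excluded_all_zero: list = field(default_factory=list)
    below_abundance_filter: list = field(default_factory=list)
    min_mean_abundance_pct: float = 1.0
    pseudocount: float = 0.5


def paired_differential_abundance(
    table: ASVTable,
    min_mean_abundance_pct: float = 1.0,
    pseudocount: float = 0.5,
    alpha: float = 0.05,
) -> DiffAbundanceResult:
    """Paired Wilcoxon + BH differential abundance on clr-transformed counts.

    For each ASV passing the abundance filter (mean relative abundance over
    all samples >= ``min_mean_abundance_pct`` %), the patientwise clr
    difference (ARG - NoARG) is tested with the exact Wilcoxon signed-rank
    test and p-values are BH-adjusted across the tested family.  Filtering
    precedes BH, so the cutoff changes the correction family (documented
    behaviour).  Also reports group mean relative abundances and the log2
    fold change of those means.
    """
    patients = table.check_paired()
    counts = np.asarray(table.counts, dtype=float)
    depth = counts.sum(axis=1, keepdims=True)
    if np.any(depth == 0):
        raise ValueError("a sample has zero total reads")
    rel = 100.0 * counts / depth

    arg_rows = np.array([
        int(np.flatnonzero((table.patient_id == p) & (table.treatment == "ARG"))[0])
        for p in patients
    ])
    noarg_rows = np.array([
        int(np.flatnonzero((table.patient_id == p) & (table.treatment == "NoARG"))[0])
        for p in patients
    ])

    clr = clr_transform(counts, pseudocount)
    clr_diff = clr[arg_rows] - clr[noarg_rows]          # patients x ASVs

    all_zero = counts.sum(axis=0) == 0
    mean_rel = rel.mean(axis=0)
    tested = ~all_zero & (mean_rel >= min_mean_abundance_pct)
    below = ~all_zero & ~tested

    rows = []
    for j in np.flatnonzero(tested):
        w, p, n_used = wilcoxon_signed_rank(clr_diff[:, j])
        mean_arg = float(rel[arg_rows, j].mean())
        mean_noarg = float(rel[noarg_rows, j].mean())
        if mean_arg > 0 and mean_noarg > 0:
            l2fc = math.log2(mean_arg / mean_noarg)
        else:
            l2fc = float("nan")
        rows.append({
            "asv": str(table.taxonomy[j]),
            "mean_rel_abundance_arg_pct": mean_arg,
            "mean_rel_abundance_noarg_pct": mean_noarg,
            "clr_effect": float(clr_diff[:, j].mean()),
            "log2_fold_change": l2fc,
            "wilcoxon_w": w,
            "p": p,
            "zero_variance": n_used == 0,
        })
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = multipletests(result["p"].to_numpy(),
                                    method="fdr_bh")[1]
        result["significant"] = result["q"] < alpha
    else:
        result["q"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return DiffAbundanceResult(
        table=result,
        excluded_all_zero=[str(t) for t in table.taxonomy[all_zero]],
        below_abundance_filter=[str(t) for t in table.taxonomy[below]],
        min_mean_abundance_pct=min_mean_abundance_pct,
        pseudocount=pseudocount,
    )


# ---------------------------------------------------------------------------
# PCA on clr counts

def pca_clr(table: ASVTable, n_components: int = 2,
            pseudocount: float = 0.5) -> tuple[np.ndarray, np.ndarray, PCA]:
    """Centred PCA of the clr-transformed count matrix.

    Returns ``(scores, explained_variance_ratio, fitted_pca)``.  Component
    signs are fixed by making each component's largest-magnitude loading
    positive, so scores are deterministic across platforms.
    """
    if table.n_samples < 3:
        raise ValueError("PCA requires at least 3 samples")
    clr = clr_transform(table.counts, pseudocount)
    n_components = min(n_components, table.n_samples - 1, table.n_asvs)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(clr)
    for k in range(pca.components_.shape[0]):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            pca.components_[k] *= -1
            scores[:, k] *= -1
    return scores, pca.explained_variance_ratio_, pca


# ---------------------------------------------------------------------------
# hierarchical (nested) inference

@dataclass
class HierarchicalResult:
    """Group means, difference and paired inference for nested FOV data."""

    group_means: dict
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    method: Literal["mixed_model", "two_stage"]
    variance_components: dict = field(default_factory=dict)
    two_stage_difference: float = float("nan")
    two_stage_p: float = float("nan")
    warnings: list = field(default_factory=list)


def _two_stage(df: pd.DataFrame, levels) -> tuple[float, float, float, dict]:
    biofilm = (df.groupby(["patient", "group", "biofilm"], sort=True)["value"]
               .mean().reset_index())
    patient = (biofilm.groupby(["patient", "group"], sort=True)["value"]
               .mean().unstack("group"))
    a = patient[levels[1]].to_numpy()
    b = patient[levels[0]].to_numpy()
    diff = a - b
    mean_diff = float(diff.mean())
    if diff.size >= 2 and diff.std(ddof=1) > 0:
        t, p = sps.ttest_rel(a, b)
        se = diff.std(ddof=1) / math.sqrt(diff.size)
        tcrit = sps.t.ppf(0.975, diff.size - 1)
        ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)
        p = float(p)
    else:
        ci = (mean_diff, mean_diff)
        p = 1.0 if mean_diff == 0 else 0.0
    means = {levels[0]: float(b.mean()), levels[1]: float(a.mean())}
    return mean_diff, p, ci, means


def hierarchical_estimate(
    measurements: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    patient: str = "patient",
    biofilm: str = "biofilm",
    reference: Optional[str] = None,
) -> HierarchicalResult:
    """Group comparison honouring FOVs nested in biofilms nested in patients.

    Fits a linear mixed model with a fixed group effect and random
    intercepts for patient and biofilm-within-patient (REML).  A two-stage
    aggregation (FOV -> biofilm -> patient means, then paired t) is always
    computed as a cross-check and used as fallback when the mixed model is
    degenerate or fails to converge; on balanced data the two routes agree
    in sign.

    ``difference`` is the non-reference minus the reference group;
    ``reference`` defaults to the alphabetically first level (pass
    ``reference="NoARG"`` to obtain the ARG - NoARG convention).
    """
    df = measurements.rename(columns={value: "value", group: "group",
                                      patient: "patient", biofilm: "biofilm"})
    df = df[["value", "group", "patient", "biofilm"]].copy()
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference {reference!r} not a group level")
        levels = [reference] + [lv for lv in levels if lv != reference]
    both = df.groupby("patient")["group"].nunique()
    if (both == 2).sum() < 2:
        raise ValueError("need >= 2 patients observed in both groups")

    ts_diff, ts_p, ts_ci, ts_means = _two_stage(df, levels)

    # degenerate layouts (one FOV per biofilm and one biofilm per side) carry
    # no replication to separate the variance components
    reps = df.groupby(["patient", "group", "biofilm"]).size()
    biofilms_per_side = df.groupby(["patient", "group"])["biofilm"].nunique()
    degenerate = (reps.max() == 1) and (biofilms_per_side.max() == 1)

    warns: list[str] = []
    if not degenerate:
        try:
            df["biofilm_uid"] = (df["patient"].astype(str) + "//"
                                 + df["biofilm"].astype(str))
            df["g"] = (df["group"] == levels[1]).astype(float)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                model = MixedLM.from_formula(
                    "value ~ g", groups="patient",
                    re_formula="1",
                    vc_formula={"biofilm": "0 + C(biofilm_uid)"},
                    data=df,
                )
                fit = model.fit(reml=True, method="lbfgs")
            if float(fit.scale) <= 1e-10 * max(float(df["value"].var()), 1e-12):
                # no residual variation below the biofilm level: the REML fit
                # is degenerate and the patient-mean aggregation is exact
                raise RuntimeError("zero residual variance")
            diff = float(fit.params["g"])
            se = float(fit.bse["g"])
            ci = (diff - 1.959963984540054 * se, diff + 1.959963984540054 * se)
            p = float(fit.pvalues["g"])
            intercept = float(fit.params["Intercept"])
            vc = {"patient": float(fit.cov_re.iloc[0, 0]),
                  "residual": float(fit.scale)}
            if getattr(fit, "vcomp", None) is not None and len(fit.vcomp):
                vc["biofilm"] = float(fit.vcomp[0])
            return HierarchicalResult(
                group_means={levels[0]: intercept, levels[1]: intercept + diff},
                difference=diff, ci_low=float(ci[0]), ci_high=float(ci[1]),
                p_value=p, method="mixed_model", variance_components=vc,
                two_stage_difference=ts_diff, two_stage_p=ts_p,
                warnings=warns,
            )
        except Exception as exc:  # singular fits fall back to aggregation
            warns.append(f"mixed model failed ({exc}); two-stage fallback used")
    else:
        warns.append("degenerate nesting; two-stage aggregation used")
    return HierarchicalResult(
        group_means=ts_means, difference=ts_diff,
        ci_low=float(ts_ci[0]), ci_high=float(ts_ci[1]), p_value=ts_p,
        method="two_stage", two_stage_difference=ts_diff, two_stage_p=ts_p,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# classical paired t, OLS, sample size

def paired_t(values_a: Sequence[float], values_b: Sequence[float]):
    """Two-sided paired t-test; returns ``(t, p, mean_difference)``.

    Zero-variance differences are flagged by a NaN t with p = 1 (identical
    vectors) — the comparison is exact, not asymptotic, in that case.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 complete pairs")
    d = a - b
    mean_diff = float(d.mean())
    if d.std(ddof=1) == 0:
        p = 1.0 if mean_diff == 0 else 0.0
        return float("nan"), p, mean_diff
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p), mean_diff


def regress(x: Sequence[float], y: Sequence[float]):
    """Simple OLS of y on x with a two-sided slope test.

    Returns ``(slope, intercept, p, r_squared)``.  Used for patient-level
    relations (e.g. ΔpH versus Δbiovolume).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("regression needs >= 3 points")
    if np.all(x == x[0]):
        raise ValueError("constant x: slope undefined")
    res = sps.linregress(x, y)
    return (float(res.slope), float(res.intercept), float(res.pvalue),
            float(res.rvalue ** 2))


def sample_size_paired(
    mean_diff: float,
    sd: float,
    alpha: float = 0.05,
    beta: float = 0.20,
    sided: Literal["two", "one"] = "two",
) -> int:
    """Paired (one-sample) sample size by the normal approximation.

    n = ceil( ((z_{1-alpha/2} + z_{1-beta}) * sd / mean_diff)^2 ), with
    z_{1-alpha} instead for a one-sided design.  ``mean_diff`` and ``sd``
    share units (e.g. mol/L hydrogen ion concentration).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValueError("alpha and beta must lie in (0, 1)")
    if mean_diff == 0:
        raise ValueError("mean_diff must be nonzero")
    z_a = sps.norm.ppf(1 - alpha / 2) if sided == "two" else sps.norm.ppf(1 - alpha)
    z_b = sps.norm.ppf(1 - beta)
    return int(math.ceil(((z_a + z_b) * sd / abs(mean_diff)) ** 2))
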