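"""Paired statistics: clr, Wilcoxon+BH, PCA, nested models, power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from biofilmq.stats import (
    ASVTable,
    clr_transform,
    hierarchical_estimate,
    paired_differential_abundance,
    paired_t,
    pca_clr,
    regress,
    sample_size_paired,
    wilcoxon_signed_rank,
)
from biofilmq.synthetic import AsvSpec, CohortSpec, gen_asv_table, gen_ph_cohort


class TestClr:
    def test_symmetric_sample_maps_to_zero(self):
        out = clr_transform(np.array([[1, 1, 1, 1]]), pseudocount=0.5)
        assert np.allclose(out, 0.0)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, (12, 40))
        out = clr_transform(counts, 0.5)
        assert np.allclose(out.sum(axis=1), 0.0, atol=1e-9)

    def test_depth_invariance_with_scaled_pseudocount(self):
        counts = np.array([[10, 30, 60]])
        a = clr_transform(counts, pseudocount=1.0)
        b = clr_transform(2 * counts, pseudocount=2.0)
        assert np.allclose(a, b)

    def test_two_part_composition_closed_form(self):
        out = clr_transform(np.array([[8, 2]]), pseudocount=0)
        assert np.allclose(out, [np.log(2), -np.log(2)])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            clr_transform(np.array([[1, -1]]))

    def test_zero_pseudocount_requires_positive_counts(self):
        with pytest.raises(ValueError):
            clr_transform(np.array([[0, 5]]), pseudocount=0)


class TestWilcoxon:
    def test_exact_p_matches_scipy(self):
        rng = np.random.default_rng(1)
        for n in (6, 10, 18, 25):
            d = rng.normal(0.3, 1.0, n)
            _, p, _ = wilcoxon_signed_rank(d)
            assert p == pytest.approx(
                sps.wilcoxon(d, method="exact").pvalue, abs=1e-12)

    def test_exact_p_matches_full_enumeration_at_n10(self):
        """Brute force: enumerate all 2^10 sign patterns of the ranks."""
        rng = np.random.default_rng(2)
        d = rng.normal(0.5, 1.0, 10)
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [sum(r for r, s in zip(ranks, signs) if s)
              for signs in itertools.product([False, True], repeat=10)]
        ws = np.array(ws)
        p_enum = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
        _, p, _ = wilcoxon_signed_rank(d)
        assert p == pytest.approx(p_enum, abs=1e-12)

    def test_all_zero_differences_flagged(self):
        w, p, n = wilcoxon_signed_rank(np.zeros(10))
        assert p == 1.0 and n == 0

    def test_zeros_dropped_before_ranking(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -0.5, 3.0, 1.5, -2.5])
        _, p, n = wilcoxon_signed_rank(d)
        assert n == 6
        assert p == pytest.approx(
            sps.wilcoxon(d, zero_method="wilcox", method="exact").pvalue,
            abs=1e-12)


class TestDifferentialAbundance:
    def test_spiked_asvs_detected(self):
        table, truth = gen_asv_table(
            AsvSpec(effect_asvs=(0, 1, 2, 3, 4), effect_log=1.5), seed=7)
        res = paired_differential_abundance(table)
        detected = set(res.table[res.table.significant].asv)
        assert len(detected & set(truth["shifted_taxa"])) >= 3

    def test_zero_variance_asv_reported_with_p_one(self):
        counts = np.tile([100, 200, 300, 400], (8, 1))
        table = ASVTable(counts=counts,
                         patient_id=np.repeat([f"P{i}" for i in range(4)], 2),
                         treatment=np.tile(["ARG", "NoARG"], 4))
        res = paired_differential_abundance(table)
        assert res.table.zero_variance.all()
        assert (res.table.p == 1.0).all()

    def test_unpaired_patient_named_in_error(self):
        counts = np.array([[10, 20], [10, 20], [5, 5]])
        table = ASVTable(counts=counts,
                         patient_id=np.array(["P1", "P1", "P2"]),
                         treatment=np.array(["ARG", "NoARG", "ARG"]))
        with pytest.raises(ValueError, match="P2"):
            paired_differential_abundance(table)

    def test_q_values_dominate_p_and_are_monotone(self):
        table, _ = gen_asv_table(AsvSpec(effect_asvs=(0, 1), effect_log=1.0),
                                 seed=3)
        res = paired_differential_abundance(table).table
        assert (res.q >= res.p - 1e-12).all()
        assert res.q.between(0, 1).all()
        ordered = res.sort_values("p")
        assert (np.diff(ordered.q) >= -1e-12).all()

    def test_all_zero_asvs_listed_not_tested(self):
        counts = np.column_stack([np.full(8, 100), np.zeros(8, dtype=int),
                                  np.full(8, 50)])
        table = ASVTable(counts=counts,
                         patient_id=np.repeat([f"P{i}" for i in range(4)], 2),
                         treatment=np.tile(["ARG", "NoARG"], 4))
        res = paired_differential_abundance(table)
        assert res.excluded_all_zero == ["ASV2"]
        assert "ASV2" not in set(res.table.asv)


class TestPcaClr:
    def test_identical_samples_identical_scores(self):
        counts = np.vstack([[10, 20, 30, 40]] * 2 + [[40, 30, 20, 10]] * 2)
        table = ASVTable(counts=counts,
                         patient_id=np.array(["P1", "P2", "P3", "P4"]),
                         treatment=np.array(["ARG", "ARG", "NoARG", "NoARG"]))
        scores, _, _ = pca_clr(table)
        assert np.allclose(scores[0], scores[1], atol=1e-9)

    def test_variance_explained_non_increasing(self):
        table, _ = gen_asv_table(seed=5)
        _, evr, _ = pca_clr(table, n_components=5)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_patient_structure_dominates_when_patient_sd_large(self):
        from sklearn.metrics import silhouette_score
        table, _ = gen_asv_table(
            AsvSpec(patient_sd=2.0, effect_asvs=(0, 1, 2), effect_log=0.3),
            seed=9)
        scores, _, _ = pca_clr(table)
        by_patient = silhouette_score(scores, table.patient_id)
        by_treatment = silhouette_score(scores, table.treatment)
        assert by_patient > by_treatment

    def test_too_few_samples_rejected(self):
        table = ASVTable(counts=np.array([[1, 2], [3, 4]]),
                         patient_id=np.array(["P1", "P1"]),
                         treatment=np.array(["ARG", "NoARG"]))
        with pytest.raises(ValueError):
            pca_clr(table)


class TestHierarchicalEstimate:
    @staticmethod
    def _balanced(diff=0.2, noise=0.0, seed=0, n_patients=6):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_patients):
            for group, mean in (("NoARG", 5.8), ("ARG", 5.8 + diff)):
                for bf in range(2):
                    for fov in range(3):
                        rows.append({
                            "patient": f"P{p}", "group": group,
                            "biofilm": f"{group}-B{bf}",
                            "value": mean + noise * rng.normal()})
        return pd.DataFrame(rows)

    def test_zero_noise_difference_exact(self):
        res = hierarchical_estimate(self._balanced(), reference="NoARG")
        assert res.difference == pytest.approx(0.2, abs=1e-9)

    def test_recovers_difference_under_nested_noise(self):
        spec = CohortSpec(patient_sd=0.3, biofilm_sd=0.1, fov_sd=0.15)
        hits = 0
        for seed in range(20):
            df = gen_ph_cohort(spec, seed=seed).query("timepoint_min == 10")
            df = df.rename(columns={"patient_id": "patient",
                                    "carrier_id": "biofilm",
                                    "treatment": "group",
                                    "mean_ph": "value"})
            res = hierarchical_estimate(df, reference="NoARG")
            if abs(res.difference - 0.19) < 0.1:
                hits += 1
        assert hits >= 18  # >= 90% of seeds

    def test_reduces_to_paired_t_without_nested_variance(self):
        df = self._balanced(diff=0.15)
        # add patient-level offsets only: FOV and biofilm variances zero
        offsets = {f"P{p}": 0.1 * p for p in range(6)}
        df["value"] += df["patient"].map(offsets)
        res = hierarchical_estimate(df, reference="NoARG")
        patient_means = df.groupby(["patient", "group"])["value"].mean().unstack()
        t, p, mean_diff = paired_t(patient_means["ARG"],
                                   patient_means["NoARG"])
        assert res.two_stage_difference == pytest.approx(mean_diff, abs=1e-12)
        assert res.difference == pytest.approx(mean_diff, abs=1e-9)

    def test_null_ci_covers_zero(self):
        spec = CohortSpec(true_delta_ph=((10, 0.0), (35, 0.0)))
        covered = 0
        for seed in range(20):
            df = gen_ph_cohort(spec, seed=100 + seed).query("timepoint_min == 10")
            df = df.rename(columns={"patient_id": "patient",
                                    "carrier_id": "biofilm",
                                    "treatment": "group",
                                    "mean_ph": "value"})
            res = hierarchical_estimate(df, reference="NoARG")
            if res.ci_low <= 0 <= res.ci_high:
                covered += 1
        assert covered >= 17  # ~95% nominal, small-sample slack

    def test_degenerate_layout_falls_back_with_warning(self):
        rows = [{"patient": f"P{p}", "group": g, "biofilm": f"{g}-B0",
                 "value": 5.8 + (0.2 if g == "ARG" else 0.0) + 0.01 * p}
                for p in range(4) for g in ("ARG", "NoARG")]
        res = hierarchical_estimate(pd.DataFrame(rows), reference="NoARG")
        assert res.method == "two_stage"
        assert res.warnings


class TestPairedT:
    def test_identical_vectors(self):
        t, p, d = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0 and d == 0.0

    def test_constant_shift_flagged_exact(self):
        t, p, d = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert d == pytest.approx(-1.0)
        assert np.isnan(t) and p == 0.0

    def test_matches_closed_form_t(self):
        rng = np.random.default_rng(4)
        a = rng.normal(6.0, 0.3, 10)
        b = rng.normal(5.8, 0.3, 10)
        t, p, d = paired_t(a, b)
        diff = a - b
        t_ref = diff.mean() / (diff.std(ddof=1) / np.sqrt(10))
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_ref), 9), abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


class TestRegress:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, p, r2 = regress(x, 2 * x)
        assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)

    def test_null_slope_p_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            ps.append(regress(x, y)[2])
        # Kolmogorov-Smirnov against U(0,1)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            regress([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSampleSize:
    def test_unit_effect_two_sided(self):
        # ceil((1.95996 + 0.84162)^2) with delta = sd
        assert sample_size_paired(1.0, 1.0, alpha=0.05, beta=0.20) == 8

    def test_hydrogen_ion_inputs_default_convention(self):
        # the classical paired normal approximation on Δ[H+] = 1.03e-7,
        # SD = 1.39e-7 gives 15 (one-sided: 12)
        assert sample_size_paired(1.03e-7, 1.39e-7) == 15
        assert sample_size_paired(1.03e-7, 1.39e-7, sided="one") == 12

    def test_stricter_alpha_never_reduces_n(self):
        ns = [sample_size_paired(0.5, 1.0, alpha=a)
              for a in (0.10, 0.05, 0.01, 0.001)]
        assert all(b >= a for a, b in zip(ns, ns[1:]))

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            sample_size_paired(0.0, 1.0)
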