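"""FLBA biovolumes: layer stratification, normalisation, thickness, CV."""

import numpy as np
import pytest

from biofilmq.flba import (
    LAYERS,
    SegConfig,
    ZStack,
    fov_variability,
    layer_slices,
    normalize,
    stack_biovolumes,
    thickness,
)
from biofilmq.synthetic import NOISELESS, NoiseModel, gen_flba_stack

FIXED = SegConfig(method="fixed", fixed_cell=110.0, fixed_lectin=110.0)


def _uniform_stack(lectin_area_px=400, cell_area_px=900, n=6, shape=(32, 32),
                   interslice=2.0):
    """Stack with identical rectangular masks in every slice (no noise)."""
    slices = np.full((n, 2) + shape, 20.0)
    for i in range(n):
        lr = int(np.sqrt(lectin_area_px))
        cr = int(np.sqrt(cell_area_px))
        slices[i, 0, :lr, :lr] = 200.0
        slices[i, 1, -cr:, -cr:] = 200.0
    return ZStack(slices=slices, interslice_um=interslice, pixel_size=1.0)


class TestLayerAssignment:
    def test_six_slices_pair_into_layers(self):
        assert layer_slices(6) == {"bottom": [0, 1], "middle": [2, 3],
                                   "top": [4, 5]}

    def test_other_counts_split_into_thirds(self):
        layers = layer_slices(9)
        assert [len(v) for v in layers.values()] == [3, 3, 3]
        assert layers["bottom"] == [0, 1, 2]


class TestStackBiovolumes:
    def test_uniform_areas_give_expected_volumes(self):
        # 100 µm² of lectin per slice at Δz = 2 µm -> 1200 µm³ total,
        # 400 µm³ per layer
        stack = _uniform_stack(lectin_area_px=100, interslice=2.0)
        report = stack_biovolumes(stack, FIXED)
        assert report.lectin_um3["total"] == pytest.approx(1200.0)
        for layer in LAYERS:
            assert report.lectin_um3[layer] == pytest.approx(400.0)

    def test_layer_additivity(self):
        stack, _ = gen_flba_stack([0.3] * 6, [0.1] * 6, shape=(48, 48), seed=1)
        report = stack_biovolumes(stack)
        for comp in (report.microbial_um3, report.lectin_um3,
                     report.intercellular_um3):
            assert sum(comp[k] for k in LAYERS) == pytest.approx(
                comp["total"], abs=1e-9)

    def test_lectin_inside_cells_yields_zero_intercellular(self):
        shape = (32, 32)
        slices = np.full((6, 2) + shape, 20.0)
        slices[:, 1, 5:20, 5:20] = 200.0   # cells
        slices[:, 0, 8:12, 8:12] = 200.0   # lectin strictly inside
        stack = ZStack(slices=slices, pixel_size=1.0)
        report = stack_biovolumes(
            stack, SegConfig("fixed", 110.0, 110.0, dilation_radius_px=0))
        assert report.intercellular_um3["total"] == 0.0

    def test_generator_stack_recovered_within_3pct(self):
        stack, truth = gen_flba_stack(
            [0.30, 0.28, 0.24, 0.18, 0.10, 0.04],
            [0.12, 0.10, 0.07, 0.05, 0.03, 0.01],
            shape=(128, 128), seed=3)
        report = stack_biovolumes(stack)
        for name, comp, ref in (
            ("microbial", report.microbial_um3, truth.microbial_um3),
            ("lectin", report.lectin_um3, truth.lectin_um3),
            ("intercellular", report.intercellular_um3,
             truth.intercellular_um3),
        ):
            for key in (*LAYERS, "total"):
                assert comp[key] == pytest.approx(ref[key], rel=0.03), (
                    f"{name} {key}")

    def test_constant_channel_error_names_slice_and_channel(self):
        stack = _uniform_stack()
        stack.slices[2, 0] = 20.0  # constant green in slice 3
        with pytest.raises(ValueError, match="slice 3, green"):
            stack_biovolumes(stack, SegConfig(method="otsu"))

    def test_volumes_scale_linearly_with_interslice(self):
        s1, _ = gen_flba_stack([0.2] * 6, [0.1] * 6, interslice_um=1.0,
                               noise=NOISELESS, shape=(48, 48), seed=5)
        s2 = ZStack(slices=s1.slices, interslice_um=2.0, pixel_size=s1.pixel_size)
        r1 = stack_biovolumes(s1, FIXED)
        r2 = stack_biovolumes(s2, FIXED)
        for key in (*LAYERS, "total"):
            assert r2.lectin_um3[key] == pytest.approx(2 * r1.lectin_um3[key])
            assert r2.microbial_um3[key] == pytest.approx(
                2 * r1.microbial_um3[key])

    def test_zero_lectin_fraction_gives_zero_lectin_volume(self):
        stack, _ = gen_flba_stack([0.2] * 6, [0.0] * 6, shape=(48, 48), seed=2)
        report = stack_biovolumes(stack, FIXED)
        assert report.lectin_um3["total"] == 0.0


class TestNormalize:
    def test_quarter_ratio(self):
        stack = _uniform_stack(lectin_area_px=100, cell_area_px=400)
        report = stack_biovolumes(stack, FIXED)
        assert report.normalized_total_pct["total"] == pytest.approx(25.0)

    def test_zero_lectin_gives_zero_pct(self):
        stack, _ = gen_flba_stack([0.2] * 6, [0.0] * 6, noise=NOISELESS,
                                  shape=(48, 48), seed=0)
        report = stack_biovolumes(stack, FIXED)
        assert report.normalized_total_pct["total"] == 0.0

    def test_equal_lectin_and_microbial_is_100pct(self):
        shape = (32, 32)
        slices = np.full((6, 2) + shape, 20.0)
        slices[:, 0, :10, :10] = 200.0
        slices[:, 1, :10, :10] = 200.0
        report = stack_biovolumes(ZStack(slices=slices, pixel_size=1.0), FIXED)
        assert report.normalized_total_pct["total"] == pytest.approx(100.0)

    def test_total_denominator_variant(self):
        stack = _uniform_stack(lectin_area_px=100, cell_area_px=400)
        report = normalize(stack_biovolumes(stack, FIXED),
                           denominator="total")
        # each layer's lectin against the whole-stack microbial biovolume
        assert report.normalized_total_pct["bottom"] == pytest.approx(
            100.0 * report.lectin_um3["bottom"] / report.microbial_um3["total"])

    def test_no_microbial_biovolume_is_undefined(self):
        shape = (32, 32)
        slices = np.full((6, 2) + shape, 20.0)
        slices[:, 0, :10, :10] = 200.0  # lectin only
        report = stack_biovolumes(ZStack(slices=slices, pixel_size=1.0), FIXED)
        assert np.isnan(report.normalized_total_pct["total"])


class TestThickness:
    def test_fully_occupied_stack(self):
        stack = _uniform_stack(interslice=5.0)
        assert thickness(stack, seg=FIXED) == pytest.approx(30.0)

    def test_partially_occupied_stack(self):
        stack = _uniform_stack(interslice=5.0)
        stack.slices[3:, 1] = 20.0  # slices 4-6 empty
        assert thickness(stack, seg=FIXED) == pytest.approx(15.0)

    def test_generator_occupancy_recovered_exactly(self):
        stack, truth = gen_flba_stack(
            [0.3, 0.2, 0.1, 0.0, 0.0, 0.0], [0.05] * 6,
            noise=NOISELESS, shape=(48, 48), interslice_um=4.0, seed=8)
        assert thickness(stack, seg=FIXED) == pytest.approx(truth.thickness_um)
        assert truth.thickness_um == pytest.approx(12.0)


class TestImposedTreatmentEffect:
    def test_arg_lectin_reduction_direction_recovered_across_seeds(self):
        """Halving lectin production on the arginine side is recovered in
        direction by the paired comparison in every tested cohort."""
        from biofilmq.synthetic import FlbaSpec, gen_cohort, reduced_cohort_spec

        spec = reduced_cohort_spec(
            flba=FlbaSpec(shape=(64, 64), fovs_per_biofilm=1))
        for seed in range(20):
            cohort = gen_cohort(spec, seed=seed)
            means = (cohort.flba_truth
                     .groupby(["patient_id", "treatment"])
                     ["lectin_total_um3"].mean().unstack())
            assert (means["ARG"] - means["NoARG"]).mean() < 0


class TestFovVariability:
    def test_constant_values_have_zero_cv(self):
        assert fov_variability([5, 5, 5]) == 0.0

    def test_two_point_cv(self):
        assert fov_variability([4, 6]) == pytest.approx(np.sqrt(2) / 5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 10, 20)
        assert fov_variability(3.7 * x) == pytest.approx(fov_variability(x))

    def test_zero_mean_undefined(self):
        assert np.isnan(fov_variability([-1.0, 1.0]))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            fov_variability([5.0])
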