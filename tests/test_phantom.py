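"""Phantom generation and reconstruction-noise rendering."""

import dataclasses

import numpy as np
import pytest

from lungqct import (
    CohortRanges,
    CTVolume,
    PhantomParams,
    ReconParams,
    apply_reconstruction,
    generate_cohort,
    generate_phantom,
)
from lungqct.phantom import draw_cohort_params


class TestGeneratePhantom:
    def test_deterministic_under_seed(self):
        p = PhantomParams(grid_shape=(64, 64, 64), seed=11)
        a_insp, a_exp, _ = generate_phantom(p)
        b_insp, b_exp, _ = generate_phantom(p)
        np.testing.assert_array_equal(a_insp.values, b_insp.values)
        np.testing.assert_array_equal(a_exp.values, b_exp.values)

    def test_emphysema_fraction_hits_target(self):
        p = PhantomParams(grid_shape=(64, 64, 64), emphysema_fraction=0.10, seed=4)
        _, _, truth = generate_phantom(p)
        achieved = truth.emphysema_mask.sum() / truth.lung_mask.sum()
        assert achieved == pytest.approx(0.10, abs=0.01)

    def test_zero_fractions_give_empty_masks(self):
        p = PhantomParams(
            grid_shape=(64, 64, 64), emphysema_fraction=0.0, trapping_fraction=0.0
        )
        _, _, truth = generate_phantom(p)
        assert truth.emphysema_mask.sum() == 0
        assert truth.trapping_mask.sum() == 0

    def test_masks_nested_and_disjoint(self, small_phantom):
        _, _, truth = small_phantom
        assert np.all(truth.lung_mask[truth.emphysema_mask])
        assert np.all(truth.lung_mask[truth.trapping_mask])
        assert not np.any(truth.emphysema_mask & truth.trapping_mask)
        # the lumen is carved out of the lung
        assert not np.any(truth.lung_mask & truth.airway_lumen_mask)

    def test_airway_truth_closed_forms(self, small_phantom):
        _, _, truth = small_phantom
        r_i, r_o = truth.airway_inner_radius_mm, truth.airway_outer_radius_mm
        assert truth.true_LA_mm2 == pytest.approx(np.pi * r_i**2, rel=1e-12)
        assert truth.true_WA_mm2 == pytest.approx(np.pi * (r_o**2 - r_i**2), rel=1e-12)
        assert truth.true_Pi_mm == pytest.approx(2 * np.pi * r_i, rel=1e-12)

    def test_expiratory_shift_and_trapping_retention(self, small_params, small_phantom):
        insp, exp, truth = small_phantom
        normal = truth.lung_mask & ~truth.emphysema_mask & ~truth.trapping_mask
        assert exp.values[normal].mean() == pytest.approx(
            small_params.hu_normal_exp, abs=2.0
        )
        assert exp.values[truth.trapping_mask].mean() == pytest.approx(
            small_params.hu_trapped_exp, abs=2.0
        )
        assert insp.values[normal].mean() == pytest.approx(
            small_params.hu_normal_insp, abs=2.0
        )

    @pytest.mark.parametrize(
        "bad",
        [
            {"emphysema_fraction": 0.7, "trapping_fraction": 0.5},
            {"airway_inner_radius_mm": 4.0, "airway_outer_radius_mm": 3.0},
            {"voxel_spacing_mm": (0.7, -0.7, 1.0)},
            {"hu_emphysema": -900.0},  # violates hu_emphysema < -950
            {"emphysema_fraction": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_phantom(dataclasses.replace(PhantomParams(), **bad))


class TestApplyReconstruction:
    def test_zero_sigma_is_identity(self, small_phantom):
        insp, _, _ = small_phantom
        out = apply_reconstruction(insp, ReconParams(label="FBP", noise_sigma_hu=0.0), 1)
        np.testing.assert_array_equal(out.values, insp.values)
        assert out.recon_label == "FBP"

    def test_noise_is_zero_mean(self):
        block = CTVolume(np.full((50, 50, 50), -880.0, np.float32), (1, 1, 1))
        out = apply_reconstruction(block, ReconParams.fbp(80.0), 7)
        delta = (out.values - block.values).astype(np.float64)
        n = delta.size
        assert abs(delta.mean()) < 3 * 80.0 / np.sqrt(n)

    def test_ir_noise_reduction_ratio(self):
        """Sample std under IR is (1 - reduction) times the FBP std."""
        block = CTVolume(np.full((50, 50, 50), -880.0, np.float32), (1, 1, 1))
        fbp = apply_reconstruction(block, ReconParams.fbp(80.0), 3)
        ir = apply_reconstruction(block, ReconParams.idose(80.0, 0.45), 4)
        ratio = ir.values.std(dtype=np.float64) / fbp.values.std(dtype=np.float64)
        assert ratio == pytest.approx(0.55, abs=0.02)

    def test_shared_seed_scales_same_noise_field(self):
        block = CTVolume(np.zeros((20, 20, 20), np.float32), (1, 1, 1))
        fbp = apply_reconstruction(block, ReconParams.fbp(80.0), 9)
        ir = apply_reconstruction(block, ReconParams.idose(80.0, 0.45), 9)
        np.testing.assert_allclose(ir.values, 0.55 * fbp.values, rtol=1e-5)

    def test_negative_sigma_rejected(self, small_phantom):
        insp, _, _ = small_phantom
        with pytest.raises(ValueError):
            apply_reconstruction(insp, ReconParams(noise_sigma_hu=-1.0), 0)


class TestGenerateCohort:
    def test_reproducible_and_distinct(self):
        base = PhantomParams(grid_shape=(64, 64, 64))
        a = list(generate_cohort(3, seed=5, base=base))
        b = list(generate_cohort(3, seed=5, base=base))
        assert [s.subject_id for s in a] == ["S001", "S002", "S003"]
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.insp.values, sb.insp.values)
        assert not np.array_equal(a[0].insp.values, a[1].insp.values)

    def test_degenerate_range_collapses(self):
        ranges = CohortRanges(emphysema_fraction=(0.07, 0.07))
        params = draw_cohort_params(5, ranges, seed=1)
        assert all(p.emphysema_fraction == pytest.approx(0.07) for p in params)

    def test_cohort_mean_near_range_midpoint(self):
        """Monte-Carlo check of the uniform draws (parameters only)."""
        lo, hi = CohortRanges().emphysema_fraction
        n = 30
        params = draw_cohort_params(n, seed=2)
        fractions = np.array([p.emphysema_fraction for p in params])
        se = (hi - lo) / np.sqrt(12 * n)
        assert abs(fractions.mean() - (lo + hi) / 2) < 3 * se

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError):
            draw_cohort_params(0)
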