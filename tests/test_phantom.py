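"""Phantom generator: geometry, rasterization and cohort simulation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from awvct.errors import GeometryError, InvalidParameterError, SimulationError
from awvct.phantom import (
    CohortSimSpec,
    PhantomSpec,
    TreeBranch,
    TreeGeometry,
    analytic_truth,
    build_tree_spec,
    rasterize_phantom,
    simulate_cohort,
)


def single_cylinder(r=2.0, length=10.0, wall=1.0):
    b = TreeBranch(0, None, (0.0, 0.0, 0.0), (0.0, 0.0, -length), r, wall, 0)
    return TreeGeometry([b], 0)


class TestTreeGeometry:
    @pytest.mark.parametrize("depth,n", [(1, 1), (2, 3), (3, 7), (4, 15)])
    def test_full_binary_tree_branch_count(self, depth, n):
        assert len(build_tree_spec(depth).branches) == 2**depth - 1 == n if depth else True

    def test_child_radius_tapers(self):
        t = build_tree_spec(2, root_radius=4.0, taper=0.8)
        for child in t.children(t.root_id):
            assert child.lumen_radius == pytest.approx(3.2)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(depth=0), dict(depth=2, root_radius=-1.0), dict(depth=2, taper=0.0), dict(depth=2, taper=1.5)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            build_tree_spec(**kwargs)

    def test_monotone_taper_enforced(self):
        branches = [
            TreeBranch(0, None, (0, 0, 0), (0, 0, -10), 2.0, 1.0, 0),
            TreeBranch(1, 0, (0, 0, -10), (0, 5, -18), 3.0, 1.0, 1),
        ]
        with pytest.raises(InvalidParameterError):
            TreeGeometry(branches, 0)

    def test_exactly_one_root_required(self):
        branches = [
            TreeBranch(0, None, (0, 0, 0), (0, 0, -10), 2.0, 1.0, 0),
            TreeBranch(1, None, (0, 0, -10), (0, 5, -18), 2.0, 1.0, 1),
        ]
        with pytest.raises(InvalidParameterError):
            TreeGeometry(branches, 0)

    def test_json_round_trip(self, tree3):
        again = TreeGeometry.from_json(tree3.to_json())
        assert len(again.branches) == len(tree3.branches)
        assert again.branch(3).lumen_radius == pytest.approx(tree3.branch(3).lumen_radius)


class TestAnalyticTruth:
    def test_single_branch_volume_area(self):
        truth = analytic_truth(single_cylinder(r=2.0, length=10.0))
        assert truth.lumen_volume_total_ml == pytest.approx(0.12566, abs=1e-4)
        assert truth.ai_mm2[0] == pytest.approx(12.566, abs=1e-3)

    def test_wa_percent_half_when_outer_area_doubles(self):
        r = 3.0
        t = r * (math.sqrt(2.0) - 1.0)
        truth = analytic_truth(single_cylinder(r=r, wall=t))
        assert truth.wa_percent[0] == pytest.approx(50.0, abs=1e-9)

    def test_subtree_volumes_sum_to_total_minus_trachea(self, tree3):
        truth = analytic_truth(tree3)
        total_subtrees = sum(truth.lumen_volume_by_subtree_ml.values())
        assert total_subtrees + truth.trachea_volume_ml == pytest.approx(truth.lumen_volume_total_ml)


class TestRasterization:
    def test_cylinder_volume_close_to_analytic(self):
        spec = PhantomSpec(shape=(96, 96, 96), blur_sigma_mm=0.0, noise_sd_hu=0.0)
        _, lumen, _, _ = rasterize_phantom(single_cylinder(r=2.0, length=10.0), spec)
        vol = lumen.values.sum() * spec.spacing[0] ** 3
        assert vol == pytest.approx(math.pi * 4.0 * 10.0, rel=0.10)

    def test_voxelization_error_shrinks_with_spacing(self):
        errors = []
        for spacing in (1.0, 0.5, 0.25):
            n = int(40 / spacing)
            spec = PhantomSpec(shape=(n, n, n), spacing=(spacing,) * 3, blur_sigma_mm=0.0, noise_sd_hu=0.0)
            _, lumen, _, _ = rasterize_phantom(single_cylinder(r=2.0, length=10.0), spec)
            vol = lumen.values.sum() * spacing**3
            errors.append(abs(vol - math.pi * 4.0 * 10.0))
        assert errors[0] > errors[1] > errors[2]

    def test_truth_masks_disjoint_and_connected(self, crisp_phantom):
        _, lumen, wall, lung = crisp_phantom
        assert not np.any(lumen.values & wall.values)
        assert not np.any(lumen.values & lung.values)
        assert not np.any(wall.values & lung.values)
        airway = lumen.values | wall.values
        _, n = ndimage.label(airway, structure=ndimage.generate_binary_structure(3, 3))
        assert n == 1

    def test_no_emphysema_means_no_low_attenuation_parenchyma(self, crisp_phantom):
        ct, _, _, lung = crisp_phantom
        assert not np.any(ct.values[lung.values] < -950.0)

    def test_emphysema_voxel_count_exact(self, emph_phantom):
        spec, (ct, _, _, lung) = emph_phantom
        n_par = int(lung.values.sum())
        n_low = int(np.count_nonzero(ct.values[lung.values] < -950.0))
        assert n_low == round(0.30 * n_par)

    def test_same_seed_bit_identical(self, tree3):
        spec = PhantomSpec(shape=(128, 128, 128), emphysema_fraction=0.1, noise_sd_hu=15.0, seed=7)
        ct1, l1, w1, g1 = rasterize_phantom(tree3, spec)
        ct2, l2, w2, g2 = rasterize_phantom(tree3, spec)
        assert np.array_equal(ct1.values, ct2.values)
        assert np.array_equal(l1.values, l2.values)

    def test_tree_exceeding_grid_raises(self):
        spec = PhantomSpec(shape=(48, 48, 48), blur_sigma_mm=0.0, noise_sd_hu=0.0)
        with pytest.raises(GeometryError):
            rasterize_phantom(build_tree_spec(4), spec)

    def test_hu_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            PhantomSpec(hu_parenchyma=-960.0)
        with pytest.raises(InvalidParameterError):
            PhantomSpec(emphysema_fraction=1.2)


class TestCohortSimulation:
    def test_zero_noise_linear_model_is_exact(self):
        spec = CohortSimSpec(n=200, noise_sd=0.0, seed=11)
        df = simulate_cohort(spec)
        names = list(spec.predictor_scales)
        Z = np.column_stack(
            [(df[c] - df[c].mean()) / df[c].std(ddof=1) for c in names if c != "tac"]
        )
        # tac is rounded to integers, so recover from the continuous columns only
        beta = spec.coefficients["rv_tlc"]
        zy = sum(
            beta.get(c, 0.0)
            * (df[c] - spec.predictor_scales[c][0]) / spec.predictor_scales[c][1]
            for c in names
            if c != "tac"
        )
        y_pred = spec.outcome_scales["rv_tlc"][0] + spec.outcome_scales["rv_tlc"][1] * zy
        resid = df["rv_tlc"] - y_pred
        # residual variance comes only from the rounded tac column
        assert resid.std() < abs(beta["tac"]) * spec.outcome_scales["rv_tlc"][1] * 1.1

    def test_null_coefficients_give_near_zero_correlation(self):
        spec = CohortSimSpec(
            n=10000,
            coefficients={"pct_fev1": {}, "rv_tlc": {}},
            noise_sd=1.0,
            seed=5,
        )
        df = simulate_cohort(spec)
        for col in ("awv_percent", "lav_percent", "age_yr"):
            r = np.corrcoef(df[col], df["pct_fev1"])[0, 1]
            assert abs(r) < 0.05

    def test_fixed_seed_reproducible(self):
        a = simulate_cohort(CohortSimSpec(n=50, seed=3))
        b = simulate_cohort(CohortSimSpec(n=50, seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_non_psd_correlation_rejected(self):
        p = len(CohortSimSpec().predictor_scales)
        bad = np.eye(p)
        bad[0, 1] = bad[1, 0] = 1.5
        with pytest.raises(SimulationError):
            CohortSimSpec(correlation=bad)

    def test_minimum_cohort_size(self):
        with pytest.raises(InvalidParameterError):
            CohortSimSpec(n=1)
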