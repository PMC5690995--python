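"""Chi-square objective and sweep-commissioning tests."""

import numpy as np
import pytest

from compqa import (
    BeamModel,
    NoiseSpec,
    SlabMeasurementSet,
    SlabRecord,
    SlabSpec,
    aggregate_optimum,
    chi2,
    commission_slabs,
    generate_slab_measurements,
    grid_search_2d,
    min_chi2_curve,
    sweep,
)
from compqa.commissioning import DEFAULT_MSF_GRID, DEFAULT_RHO_GRID

from conftest import TRUTH_MSF, TRUTH_RHO


def chi2_loop(p, x):
    """Independent elementwise evaluation of the goodness-of-fit sum."""
    total = 0.0
    for pi, xi in zip(p, x):
        total += (pi - xi) ** 2 / abs(xi)
    return total


class TestChi2:
    def test_identity_is_zero(self):
        x = np.array([-0.3, -0.9, -1.5])
        assert chi2(x, x) == 0.0

    def test_single_term_hand_value(self):
        p = np.array([-0.4, -0.9, -1.5])
        x = np.array([-0.3, -0.9, -1.5])
        assert chi2(p, x) == pytest.approx(0.01 / 0.3, rel=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = -rng.uniform(0.05, 2.0, size=3)
            p = x + rng.normal(0, 0.1, size=3)
            assert chi2(p, x) == pytest.approx(chi2_loop(p, x), abs=1e-12)

    def test_nonnegative_and_zero_only_at_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = -rng.uniform(0.05, 2.0, size=4)
            p = x + rng.normal(0, 0.05, size=4)
            v = chi2(p, x)
            assert v >= 0.0
            if not np.array_equal(p, x):
                assert v > 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            chi2([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            chi2([1.0], [0.0])
        with pytest.raises(ValueError):
            chi2([], [])


class TestMeasurementSet:
    def test_duplicate_record_rejected(self):
        rec = SlabRecord(SlabSpec(1.0, 10.0, 10.0), -0.3)
        with pytest.raises(ValueError, match="duplicate"):
            SlabMeasurementSet([rec, rec])

    def test_positive_log_ratio_at_nonzero_thickness_rejected(self):
        with pytest.raises(ValueError):
            SlabRecord(SlabSpec(1.0, 10.0, 10.0), 0.1)

    def test_fit_data_excludes_open_field_rows(self):
        recs = [
            SlabRecord(SlabSpec(0.0, 10.0, 10.0), 0.0),
            SlabRecord(SlabSpec(1.0, 10.0, 10.0), -0.3),
        ]
        slabs, x = SlabMeasurementSet(recs).fit_data()
        assert [s.thickness for s in slabs] == [1.0]
        np.testing.assert_array_equal(x, [-0.3])


def _noise_free_set(rho, msf, thicknesses=(0.0, 1.0, 3.0, 5.0),
                    depths=(10.0,), field_sizes=(10.0,)):
    truth = BeamModel(rho=rho, msf=msf)
    return generate_slab_measurements(
        truth, thicknesses, depths, field_sizes, NoiseSpec()
    )


class TestSweep:
    def test_self_consistency_at_truth(self):
        """Data generated at (8.3, 0.2): the MSF sweep lands on 0.2 with chi2=0."""
        measured = _noise_free_set(8.3, 0.2)
        grid = np.round(np.arange(0.0, 0.5 + 1e-9, 0.05), 10)
        res = sweep(measured, ("rho", 8.3), grid)
        assert res.argmin_value == pytest.approx(0.2, abs=1e-12)
        assert res.argmin_objective == pytest.approx(0.0, abs=1e-18)

    def test_matches_exhaustive_evaluation(self):
        """Sweeping at a wrong fixed density equals a naive exhaustive loop."""
        measured = _noise_free_set(8.3, 0.2)
        grid = np.round(np.arange(0.0, 0.5 + 1e-9, 0.05), 10)
        res = sweep(measured, ("rho", 8.498), grid)
        slabs, x = measured.fit_data()
        naive = []
        for g in grid:
            model = BeamModel(rho=8.498, msf=float(g))
            p = [np.log(
                (1 + model.msf * s.thickness)
                * np.exp(-model.kappa * model.rho * s.thickness)
            ) for s in slabs]
            naive.append(chi2_loop(p, x))
        np.testing.assert_allclose(res.objective, naive, rtol=1e-12)
        assert res.argmin_value == grid[int(np.argmin(naive))]

    def test_interior_point_wins_on_straddling_grid(self):
        measured = _noise_free_set(8.3, 0.2)
        res = sweep(measured, ("rho", 8.3), np.array([0.1, 0.2, 0.3]))
        assert res.argmin_value == 0.2

    def test_errors(self):
        measured = _noise_free_set(8.3, 0.2)
        with pytest.raises(ValueError):
            sweep(measured, ("rho", 8.3), np.array([]))
        with pytest.raises(ValueError):
            sweep(measured, ("kappa", 0.037), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            sweep(measured, ("rho", 8.3), np.array([0.2, 0.1]))


class TestMinChi2Curve:
    def test_exact_recovery_on_grid(self):
        measured = _noise_free_set(TRUTH_RHO, TRUTH_MSF)
        curve = min_chi2_curve(measured)
        assert curve.argmin_value == pytest.approx(TRUTH_RHO, abs=1e-12)
        assert curve.argmin_objective == pytest.approx(0.0, abs=1e-18)

    def test_off_grid_density_within_one_step(self):
        """rho off-grid by half a step (msf on-grid) resolves to a neighbor.

        When *both* parameters sit off-grid the chi-square valley runs
        along the correlated (rho, msf) direction and the argmin can land
        several steps away at the default resolution; the refinement test
        below covers that regime.
        """
        measured = _noise_free_set(7.85, 0.1)
        curve = min_chi2_curve(measured)
        assert abs(curve.argmin_value - 7.85) <= 0.1 + 1e-12

    def test_equals_reduced_2d_brute_force(self):
        measured = _noise_free_set(8.1, 0.15)
        curve = min_chi2_curve(measured)
        surface, _ = grid_search_2d(measured)
        np.testing.assert_allclose(curve.objective, surface.min(axis=1), rtol=1e-13)

    def test_invariant_to_record_permutation(self):
        measured = _noise_free_set(8.0, 0.1)
        rng = np.random.default_rng(5)
        recs = list(measured.records)
        rng.shuffle(recs)
        shuffled = SlabMeasurementSet(recs)
        c1 = min_chi2_curve(measured)
        c2 = min_chi2_curve(shuffled)
        # summation order changes at machine precision only
        np.testing.assert_allclose(c1.objective, c2.objective, rtol=1e-12)
        assert c1.argmin_value == c2.argmin_value

    def test_refinement_never_hurts(self):
        """Halving both grid steps does not increase the recovery error."""
        measured = _noise_free_set(7.84, 0.12)
        for factor in (1, 2, 4):
            rho_grid = np.round(np.arange(7.0, 9.0 + 1e-9, 0.1 / factor), 12)
            msf_grid = np.round(np.arange(0.0, 0.5 + 1e-9, 0.05 / factor), 12)
            err = abs(
                min_chi2_curve(measured, rho_grid, msf_grid).argmin_value - 7.84
            )
            if factor == 1:
                prev = err
            else:
                assert err <= prev + 1e-12
                prev = err


class TestAggregate:
    def test_single_curve_passthrough(self):
        measured = _noise_free_set(TRUTH_RHO, TRUTH_MSF)
        curve = min_chi2_curve(measured)
        res = aggregate_optimum({(10.0, 10.0): curve})
        assert res.rho_overall == curve.argmin_value

    def test_mean_is_arithmetic(self):
        measured = _noise_free_set(TRUTH_RHO, TRUTH_MSF)
        base = min_chi2_curve(measured)
        curves = {}
        for k, argmin in enumerate((7.9, 7.9, 7.9, 7.3, 8.1)):
            curves[(10.0, 5.0 + k)] = type(base)(
                parameter="rho", grid=base.grid, objective=base.objective,
                argmin_value=argmin, argmin_objective=0.0,
            )
        res = aggregate_optimum(curves)
        assert res.rho_overall == pytest.approx((7.9 * 3 + 7.3 + 8.1) / 5, rel=1e-14)

    def test_depth_strata_means(self):
        measured = _noise_free_set(TRUTH_RHO, TRUTH_MSF)
        base = min_chi2_curve(measured)

        def fake(argmin):
            return type(base)(
                parameter="rho", grid=base.grid, objective=base.objective,
                argmin_value=argmin, argmin_objective=0.0,
            )

        curves = {(2.5, 10.0): fake(7.6), (10.0, 10.0): fake(8.0),
                  (10.0, 20.0): fake(7.8)}
        res = aggregate_optimum(curves)
        assert res.rho_by_depth[2.5] == 7.6
        assert res.rho_by_depth[10.0] == pytest.approx(7.9)
        assert res.rho_overall == pytest.approx((7.6 + 8.0 + 7.8) / 3)

    def test_nine_condition_parameter_recovery(self, truth_model, noise_free_slabs):
        """3 depths x 3 field sizes from one truth: aggregate recovers it."""
        res = commission_slabs(noise_free_slabs)
        assert res.rho_overall == pytest.approx(TRUTH_RHO, abs=1e-9)
        assert res.msf_opt == pytest.approx(TRUTH_MSF, abs=1e-12)
        assert all(
            abs(v - TRUTH_RHO) < 1e-12 for v in res.per_condition_rho.values()
        )


class TestStochasticRecovery:
    def test_median_error_within_one_grid_step(self):
        """0.5% reading noise: median recovered-rho error below 0.1 g/cm^3."""
        truth = BeamModel(rho=TRUTH_RHO, msf=TRUTH_MSF)
        errs = []
        for seed in range(100):
            measured = generate_slab_measurements(
                truth, noise=NoiseSpec(relative_sd=0.005, seed=seed)
            )
            res = commission_slabs(measured)
            errs.append(abs(res.rho_overall - TRUTH_RHO))
        assert np.median(errs) <= 0.1
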