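import numpy as np
import pytest
from scipy.optimize import nnls

from lvpet import kinetics as kin
from lvpet import phantom as ph

from oracles import quadrature_tac


def analytic_curves(cfg=None):
    cfg = cfg or ph.PhantomConfig()
    return (lambda t: ph.blood_curves(cfg, t)[0], lambda t: ph.blood_curves(cfg, t)[1])


class TestSimulateTac:
    def test_pure_arterial_blood_equals_frame_averaged_ca(self, blood_inputs, frame_times):
        starts, ends = frame_times
        tac = kin.simulate_tac(0.0, 1.0, 1.0, 0.0, blood_inputs, starts, ends)
        ca_func, _ = analytic_curves()
        expected = quadrature_tac(0, 1, 1, 0, ca_func, ca_func, starts, ends)
        np.testing.assert_allclose(tac, expected, rtol=5e-3, atol=1e-3 * expected.max())

    def test_no_flow_no_spill_gives_zero_tac(self, blood_inputs, frame_times):
        starts, ends = frame_times
        tac = kin.simulate_tac(0.0, 1.0, 0.0, 0.0, blood_inputs, starts, ends)
        np.testing.assert_array_equal(tac, 0.0)

    def test_matches_independent_quadrature_within_half_percent(
        self, blood_inputs, frame_times
    ):
        starts, ends = frame_times
        tac = kin.simulate_tac(0.9, 0.91, 0.3, 0.1, blood_inputs, starts, ends)
        ca_func, cv_func = analytic_curves()
        expected = quadrature_tac(0.9, 0.91, 0.3, 0.1, ca_func, cv_func, starts, ends)
        assert np.max(np.abs(tac - expected)) <= 0.005 * expected.max()

    def test_invalid_spill_over_rejected(self, blood_inputs, frame_times):
        starts, ends = frame_times
        with pytest.raises(ValueError, match="spill-over"):
            kin.simulate_tac(1.0, 1.0, 0.7, 0.5, blood_inputs, starts, ends)
        with pytest.raises(ValueError, match="V_T"):
            kin.simulate_tac(1.0, 0.0, 0.1, 0.1, blood_inputs, starts, ends)


class TestFit:
    @pytest.mark.parametrize(
        "theta",
        [
            (0.9, 0.91, 0.3, 0.1),
            (0.3, 0.6, 0.0, 0.4),
            (2.5, 1.1, 0.5, 0.2),
        ],
    )
    def test_noiseless_round_trip_recovers_parameters(self, blood_inputs, frame_times, theta):
        starts, ends = frame_times
        mbf, vt, va, vv = theta
        tac = kin.simulate_tac(mbf, vt, va, vv, blood_inputs, starts, ends)
        fit = kin.fit_tacs(tac[None, :], blood_inputs, starts, ends)
        assert fit["mbf"][0] == pytest.approx(mbf, rel=0.02)
        assert fit["va"][0] == pytest.approx(va, abs=max(0.02 * va, 0.01))
        assert fit["vv"][0] == pytest.approx(vv, abs=max(0.02 * vv, 0.01))

    def test_blood_voxel_fits_as_pure_arterial(self, blood_inputs, frame_times):
        starts, ends = frame_times
        tac = kin.simulate_tac(0.0, 1.0, 1.0, 0.0, blood_inputs, starts, ends)
        fit = kin.fit_tacs(tac[None, :], blood_inputs, starts, ends)
        assert fit["va"][0] == pytest.approx(1.0, abs=0.02)
        assert fit["vv"][0] == pytest.approx(0.0, abs=0.02)

    def test_zero_tac_flagged_unfitted(self, blood_inputs, frame_times):
        starts, ends = frame_times
        fit = kin.fit_tacs(np.zeros((1, len(starts))), blood_inputs, starts, ends)
        assert not fit["fitted"][0]
        assert fit["rss"][0] == 0.0

    def test_grid_solution_is_optimal_among_grid_candidates(self, blood_inputs, frame_times):
        """Exhaustively re-solve every k2 candidate with scipy's NNLS and
        check the returned RSS is the grid minimum."""
        starts, ends = frame_times
        rng = np.random.default_rng(5)
        tac = kin.simulate_tac(1.2, 0.9, 0.25, 0.15, blood_inputs, starts, ends)
        tac = np.clip(tac * (1 + 0.05 * rng.standard_normal(tac.shape)), 0, None)
        k2_grid = kin.default_k2_grid(n=16)
        fit = kin.fit_tacs(tac[None, :], blood_inputs, starts, ends, k2_grid=k2_grid)
        basis, ca_bar, cv_bar = kin._basis_matrix(blood_inputs, starts, ends, k2_grid, 1.0)
        best = np.inf
        for j in range(len(k2_grid)):
            X = np.column_stack([basis[j], ca_bar, cv_bar])
            beta, _ = nnls(X, tac)
            if beta[1] + beta[2] <= 1.0:
                resid = tac - X @ beta
                best = min(best, resid @ resid)
        assert fit["rss"][0] <= best + 1e-6 * best

    def test_noise_does_not_shrink_expected_rss(self, blood_inputs, frame_times):
        starts, ends = frame_times
        tac = kin.simulate_tac(0.9, 0.91, 0.2, 0.1, blood_inputs, starts, ends)
        rng = np.random.default_rng(11)
        rss0 = kin.fit_tacs(tac[None, :], blood_inputs, starts, ends)["rss"][0]
        noisy = np.clip(
            tac[None, :] * (1 + 0.05 * rng.standard_normal((20, len(tac)))), 0, None
        )
        rss_noisy = kin.fit_tacs(noisy, blood_inputs, starts, ends)["rss"]
        assert rss_noisy.mean() > rss0

    def test_parametric_maps_invariants_enforced(self):
        with pytest.raises(ValueError, match="spill-over"):
            kin.ParametricMaps(
                mbf=np.zeros((2, 2, 2)),
                vt=np.zeros((2, 2, 2)),
                va=np.full((2, 2, 2), 0.8),
                vv=np.full((2, 2, 2), 0.5),
                rss=np.zeros((2, 2, 2)),
                fitted=np.ones((2, 2, 2), bool),
            )


class TestInputExtraction:
    def test_recovers_arterial_curve_from_phantom(self, small_dynamic):
        dynamic, inputs, _ = small_dynamic
        est = kin.extract_input_functions(dynamic)
        rms = np.sqrt(np.mean((est.ca - inputs.ca) ** 2)) / inputs.ca.max()
        assert rms <= 0.10

    def test_venous_peak_precedes_arterial_peak(self, small_dynamic):
        dynamic, _, _ = small_dynamic
        est = kin.extract_input_functions(dynamic)
        t_cv = est.times[np.argmax(est.cv)]
        t_ca = est.times[np.argmax(est.ca)]
        assert t_cv <= t_ca

    def test_flat_series_raises_no_bolus(self, frame_times):
        from lvpet.imaging import DynamicSeries, VoxelGrid3D

        starts, ends = frame_times
        frames = tuple(VoxelGrid3D(np.zeros((6, 6, 6))) for _ in starts)
        dyn = DynamicSeries(frames, starts, ends)
        with pytest.raises(kin.NoBolusError):
            kin.extract_input_functions(dyn)

    def test_input_functions_reject_late_venous_peak(self):
        t = np.arange(1.0, 11.0)
        ca = np.exp(-((t - 3) ** 2))
        cv = np.exp(-((t - 8) ** 2))
        with pytest.raises(ValueError, match="venous peak"):
            kin.InputFunctions(times=t, ca=ca, cv=cv)
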