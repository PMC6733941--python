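import numpy as np
import pytest

from vesolv import fcs
from vesolv.fcs import (
    CorrelationCurve,
    calibrate_focus,
    correct_to_25C,
    diffusion_coefficient,
    fcs_model,
    fit_fcs,
    hydrodynamic_radius,
    multitau_correlate,
    reject_outlier_curves,
    titration_slope,
    water_viscosity,
)
from vesolv.synthetic import FcsSimParams, generate_fcs_trace


# ------------------------------------------------------------------ oracle
def brute_force_multitau(counts, bin_dt, m_per_level=16, n_levels=20):
    """Transparent re-implementation of the multi-tau estimator with
    explicit loops: direct products, symmetric normalization, pairwise
    coarsening. Independent of the vectorized production code path."""
    data = [float(x) for x in counts]
    lags, G = [], []
    width = bin_dt
    level = 0
    while True:
        ks = range(1, m_per_level + 1) if level == 0 else range(m_per_level // 2 + 1, m_per_level + 1)
        for k in ks:
            n = len(data) - k
            if n <= 0:
                break
            num = sum(data[i] * data[i + k] for i in range(n)) / n
            ml = sum(data[:n]) / n
            mr = sum(data[k:]) / n
            lags.append(k * width)
            G.append(num / (ml * mr))
        level += 1
        half = len(data) // 2
        if half < m_per_level + 1 or level >= n_levels:
            break
        data = [(data[2 * i] + data[2 * i + 1]) / 2 for i in range(half)]
        width *= 2
    return np.array(lags), np.array(G)


def model_curve(N, tau_D, Omega, A_T=0.0, tau_T=1e-6, b0=0.0, n_lags=80):
    lags = np.logspace(np.log10(tau_D / 100), np.log10(tau_D * 100), n_lags)
    G = fcs_model(lags, N, tau_D, Omega, A_T, tau_T, b0)
    return CorrelationCurve(lags, G, np.full(n_lags, 10_000))


class TestMultitau:
    def test_constant_trace_gives_unity(self):
        curve = multitau_correlate(np.full(5000, 7.0), 1e-4)
        np.testing.assert_allclose(curve.G, 1.0, rtol=1e-12)

    def test_zero_trace_rejected(self):
        with pytest.raises(ValueError):
            multitau_correlate(np.zeros(5000), 1e-4)

    def test_independent_poisson_flat_within_3se(self):
        rng = np.random.default_rng(21)
        n, mu, n_seg = 200_000, 5.0, 20
        counts = rng.poisson(mu, n).astype(float)
        full = multitau_correlate(counts, 1e-4, n_levels=6)
        # SE oracle: correlate 20 independent segments, SEM of their G values
        segs = [
            multitau_correlate(seg, 1e-4, n_levels=6)
            for seg in np.array_split(counts, n_seg)
        ]
        n_shared = min(len(s.G) for s in segs + [full])
        seg_G = np.array([s.G[:n_shared] for s in segs])
        sem = seg_G.std(axis=0, ddof=1) / np.sqrt(n_seg)
        assert np.all(np.abs(full.G[:n_shared] - 1.0) < 3 * sem + 1e-4)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(4.0, 10_000).astype(float)
        curve = multitau_correlate(counts, 1e-3)
        lags, G = brute_force_multitau(counts, 1e-3)
        np.testing.assert_allclose(curve.lags, lags, rtol=1e-12)
        np.testing.assert_allclose(curve.G, G, rtol=1e-12)

    def test_level0_equals_plain_direct_correlation(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(3.0, 5000).astype(float)
        curve = multitau_correlate(counts, 1e-3)
        for k in range(1, 17):
            left, right = counts[:-k], counts[k:]
            direct = (left * right).mean() / (left.mean() * right.mean())
            assert curve.G[k - 1] == pytest.approx(direct, rel=1e-12)

    def test_lag_grid_structure(self):
        counts = np.random.default_rng(5).poisson(2.0, 4096).astype(float)
        curve = multitau_correlate(counts, 1e-3, m_per_level=16)
        assert np.all(np.diff(curve.lags) > 0)
        np.testing.assert_allclose(curve.lags[:16], 1e-3 * np.arange(1, 17))


class TestFitFcs:
    def test_noiseless_round_trip(self):
        curve = model_curve(N=5.0, tau_D=8e-3, Omega=5.0)
        fit = fit_fcs(curve)
        assert fit.converged
        assert fit.N == pytest.approx(5.0, rel=1e-8)
        assert fit.tau_D == pytest.approx(8e-3, rel=1e-8)
        assert fit.Omega == pytest.approx(5.0, rel=1e-6)

    def test_amplitude_occupancy_invariant(self):
        for N in (0.5, 2.0, 10.0):
            curve = model_curve(N=N, tau_D=1e-3, Omega=4.0)
            fit = fit_fcs(curve, fix_Omega=4.0)
            amplitude = fcs_model(curve.lags[0] * 1e-6, N, 1e-3, 4.0) - 1.0
            assert 1.0 / fit.N == pytest.approx(amplitude, rel=0.05)

    def test_triplet_round_trip(self):
        curve = model_curve(N=2.0, tau_D=5e-3, Omega=5.0, A_T=0.3, tau_T=2e-5)
        fit = fit_fcs(curve, fix_Omega=5.0, fit_triplet=True)
        assert fit.A_T == pytest.approx(0.3, rel=1e-6)
        assert fit.tau_T == pytest.approx(2e-5, rel=1e-6)

    def test_triplet_recovery_from_simulation(self):
        params = FcsSimParams(
            D=0.27e-6**2 / (4 * 2e-4), mean_N=0.15, brightness=6e6,
            A_T=0.5, tau_T=2e-5, duration=4.0, bin_dt=4e-6,
        )
        counts = generate_fcs_trace(params, seed=6)
        curve = multitau_correlate(counts, params.bin_dt)
        fit = fit_fcs(curve, fix_Omega=params.Omega, fit_triplet=True)
        assert fit.A_T == pytest.approx(0.5, rel=0.2)
        assert fit.tau_D == pytest.approx(2e-4, rel=0.15)

    def test_triplet_diffusion_mixing_warns(self):
        curve = model_curve(N=2.0, tau_D=1e-3, Omega=5.0, A_T=0.4, tau_T=8e-4)
        with pytest.warns(UserWarning, match="triplet"):
            fit_fcs(curve, fix_Omega=5.0, fit_triplet=True)


class TestCalibration:
    TAU_REF = 0.27e-6**2 / (4 * 4.6e-10)  # 39.6 us for the reference dye

    def test_reference_dye_reproduces_omega_xy(self):
        curve = model_curve(N=3.0, tau_D=self.TAU_REF, Omega=4.84)
        cal = calibrate_focus(curve, D_ref=4.6e-10)
        assert cal.omega_xy == pytest.approx(0.27e-6, rel=1e-6)

    def test_focal_volume(self):
        curve = model_curve(N=3.0, tau_D=self.TAU_REF, Omega=4.84)
        cal = calibrate_focus(curve, D_ref=4.6e-10, fix_Omega=4.84)
        assert cal.V * 1e18 == pytest.approx(0.53, abs=0.005)  # um^3

    def test_omega_scales_sqrt_D(self):
        curve = model_curve(N=3.0, tau_D=self.TAU_REF, Omega=4.84)
        cal1 = calibrate_focus(curve, D_ref=4.6e-10)
        cal2 = calibrate_focus(curve, D_ref=9.2e-10)
        assert cal2.omega_xy == pytest.approx(cal1.omega_xy * np.sqrt(2), rel=1e-9)


class TestSizing:
    def test_calibration_round_trip(self):
        assert diffusion_coefficient(3.96196e-5, 0.27e-6) == pytest.approx(
            4.6e-10, rel=1e-4
        )

    def test_vesicle_diffusion_coefficient(self):
        assert diffusion_coefficient(8e-3, 0.27e-6) == pytest.approx(2.278e-12, rel=1e-3)

    def test_omega_quadratic(self):
        assert diffusion_coefficient(1e-3, 2 * 0.27e-6) == pytest.approx(
            4 * diffusion_coefficient(1e-3, 0.27e-6), rel=1e-12
        )

    def test_vesicle_radius(self):
        # tau_D = 8 ms in the calibrated focus -> ~108 nm radius, ~215 nm diameter
        res = hydrodynamic_radius(2.278e-12, T=298.15, eta=0.89e-3)
        assert res.R_h * 1e9 == pytest.approx(107.9, abs=0.5)

    def test_radius_halves_when_D_doubles(self):
        r1 = hydrodynamic_radius(1e-12).R_h
        r2 = hydrodynamic_radius(2e-12).R_h
        assert r2 == pytest.approx(r1 / 2, rel=1e-12)

    def test_small_molecule_scale(self):
        res = hydrodynamic_radius(4.6e-10)
        assert res.R_h * 1e9 == pytest.approx(0.53, abs=0.02)


class TestTemperatureCorrection:
    def test_identity_at_25C(self):
        assert correct_to_25C(1e-12, 298.15) == pytest.approx(1e-12, rel=1e-12)

    def test_20C_factor(self):
        # viscosity-table check: (1.002/0.890) * (298.15/293.15) ~ 1.14
        factor = correct_to_25C(1.0, 293.15)
        assert factor == pytest.approx(1.14, abs=0.01)

    def test_monotone_in_temperature(self):
        factors = [correct_to_25C(1.0, T) for T in (288.15, 293.15, 298.15, 303.15)]
        assert all(a > b for a, b in zip(factors, factors[1:]))

    def test_viscosity_anchors(self):
        assert water_viscosity(293.15) == pytest.approx(1.002e-3, rel=1e-6)
        assert water_viscosity(298.15) == pytest.approx(0.890e-3, rel=1e-3)


class TestTitrationSlope:
    def test_200nm_series(self):
        # printed baseline 8.0 ms with ~8%/~18% increases
        slope, stderr, _ = titration_slope([0.0, 0.1, 0.2], [8000.0, 8640.0, 9440.0])
        assert slope == pytest.approx(7200.0, rel=1e-12)
        assert abs(slope - 7000.0) < 1400.0

    def test_100nm_series(self):
        slope, _, _ = titration_slope([0.0, 0.1, 0.2], [6100.0, 6893.0, 8174.0])
        assert slope == pytest.approx(10370.0, rel=1e-12)
        assert abs(slope - 9400.0) < 1400.0

    def test_constant_series(self):
        slope, _, _ = titration_slope([0.0, 0.1, 0.2], [5000.0, 5000.0, 5000.0])
        assert slope == 0.0


class TestOutlierRejection:
    def _noisy_model_curve(self, N, seed):
        rng = np.random.default_rng(seed)
        curve = model_curve(N=N, tau_D=1e-3, Omega=5.0)
        G = curve.G + rng.normal(0, 1e-4, curve.G.size)
        return CorrelationCurve(curve.lags, G, curve.n_samples)

    def test_homogeneous_batch_untouched(self):
        curves = [self._noisy_model_curve(2.0, s) for s in range(8)]
        kept, rejected = reject_outlier_curves(curves, fix_Omega=5.0)
        assert rejected == []
        assert len(kept) == 8

    def test_aggregate_transit_removed(self):
        curves = [self._noisy_model_curve(2.0, s) for s in range(7)]
        curves.append(self._noisy_model_curve(0.2, 99))  # 10x amplitude spike
        kept, rejected = reject_outlier_curves(curves, fix_Omega=5.0)
        assert rejected == [7]
        assert len(kept) == 7

    def test_tiny_batch_disabled_with_warning(self):
        curves = [self._noisy_model_curve(2.0, s) for s in range(2)]
        with pytest.warns(UserWarning, match="fewer than 3"):
            kept, rejected = reject_outlier_curves(curves)
        assert len(kept) == 2 and rejected == []


class TestFullChain:
    @pytest.mark.parametrize("r_nm", [50.0, 100.0])
    def test_simulate_correlate_fit_size(self, r_nm):
        """Stokes-Einstein -> Brownian sim -> correlate -> fit -> size."""
        from scipy import constants

        D = constants.k * 298.15 / (6 * np.pi * 0.89e-3 * r_nm * 1e-9)
        tau_d = 0.27e-6**2 / (4 * D)
        params = FcsSimParams(
            D=D, mean_N=0.4, brightness=3e5, duration=80.0, bin_dt=tau_d / 20,
        )
        counts = generate_fcs_trace(params, seed=int(r_nm))
        curve = multitau_correlate(counts, params.bin_dt)
        fit = fit_fcs(curve, fix_Omega=params.Omega)
        D_fit = diffusion_coefficient(fit.tau_D, 0.27e-6)
        r_fit = hydrodynamic_radius(D_fit).R_h * 1e9
        assert r_fit == pytest.approx(r_nm, rel=0.10)
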