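"""Fitting: single-species inversion, two-component decomposition, extraction."""

import numpy as np
import pytest

from ckics import (
    FitError,
    KICSCorrelation,
    TwoComponentFit,
    WindowError,
    extract_parameters,
    fit_single_species,
    fit_two_component,
    fit_two_free_species,
    normalize_cf,
)


def make_cf(values, k2, tau, normalized=False):
    return KICSCorrelation(
        k2_grid=np.asarray(k2, float),
        tau_grid=np.asarray(tau, float),
        values=np.asarray(values, float),
        n_pairs=1000 - np.arange(len(tau)),
        pixel_size=0.1,
        normalized=normalized,
    )


class TestSingleSpecies:
    def exact_cf(self, D=0.01, omega0=0.4, n_tau=11):
        k2 = np.linspace(1, 60, 24)
        tau = np.arange(n_tau, dtype=float)
        values = np.exp(-k2[None, :] * (D * tau[:, None] + omega0**2 / 4))
        return make_cf(values, k2, tau)

    def test_exact_inversion(self):
        D, omega0 = fit_single_species(self.exact_cf(D=0.01, omega0=0.4))
        assert D == pytest.approx(0.01, rel=1e-8)
        assert omega0 == pytest.approx(0.4, rel=1e-8)

    def test_static_species_gives_zero_D(self):
        D, omega0 = fit_single_species(self.exact_cf(D=0.0, omega0=0.4))
        assert D == pytest.approx(0.0, abs=1e-12)
        assert omega0 == pytest.approx(0.4, rel=1e-8)

    def test_rejects_normalized_cf(self):
        cf = self.exact_cf()
        cf.normalized = True
        with pytest.raises(ValueError):
            fit_single_species(cf)

    def test_tau_range_restriction(self):
        D, _ = fit_single_species(self.exact_cf(), tau_range=(0.0, 5.0))
        assert D == pytest.approx(0.01, rel=1e-8)

    def test_too_few_taus(self):
        cf = self.exact_cf(n_tau=2)
        with pytest.raises(ValueError):
            fit_single_species(cf)

    def test_nonfinite_inputs_raise_fit_error(self):
        cf = self.exact_cf()
        cf.values[2] = 0.0  # ln undefined everywhere on this row
        with pytest.raises(FitError):
            fit_single_species(cf)


class TestTwoComponent:
    def exact_two_gauss(self, aM=0.5, gM_rate=0.1, amu=0.5, gmu_rate=0.01, n_tau=21):
        k2 = np.linspace(0.5, 100, 40)
        tau = np.arange(n_tau, dtype=float)
        vals = np.ones((n_tau, len(k2)))
        for i, t in enumerate(tau[1:], start=1):
            vals[i] = aM * np.exp(-k2 * gM_rate * t) + amu * np.exp(-k2 * gmu_rate * t)
        return make_cf(vals, k2, tau, normalized=True)

    def test_exact_inversion_to_four_digits(self):
        cf = self.exact_two_gauss()
        fit = fit_two_component(cf, k2_range=(0, 100))
        # at τ = 1 the components are 0.5·e^(−0.1k²) + 0.5·e^(−0.01k²)
        row = 0
        assert fit.converged[row] and not fit.merged[row]
        assert fit.A_M[row] == pytest.approx(0.5, rel=1e-4)
        assert fit.A_mu[row] == pytest.approx(0.5, rel=1e-4)
        assert fit.g_M[row] == pytest.approx(0.1, rel=1e-4)
        assert fit.g_mu[row] == pytest.approx(0.01, rel=1e-4)

    def test_labeling_invariant(self):
        fit = fit_two_component(self.exact_two_gauss(), k2_range=(0, 100))
        ok = fit.converged
        assert np.all(fit.g_M[ok] >= fit.g_mu[ok])
        assert np.all(fit.A_M[ok] >= 0) and np.all(fit.A_mu[ok] >= 0)

    def test_requires_normalized(self):
        cf = self.exact_two_gauss()
        cf.normalized = False
        with pytest.raises(ValueError):
            fit_two_component(cf)

    def test_requires_enough_bins(self):
        cf = self.exact_two_gauss()
        with pytest.raises(ValueError):
            fit_two_component(cf, k2_range=(0.0, 10.0))


class TestExtract:
    def fit_with(self, g_M, g_mu, A_M=None, A_mu=None, merged=None):
        n = len(g_M)
        ones = np.ones(n)
        return TwoComponentFit(
            tau=np.arange(1, n + 1, dtype=float),
            A_M=0.4 * ones if A_M is None else np.asarray(A_M, float),
            A_mu=0.6 * ones if A_mu is None else np.asarray(A_mu, float),
            g_M=np.asarray(g_M, float),
            g_mu=np.asarray(g_mu, float),
            se_g_M=0.01 * ones,
            se_g_mu=0.01 * ones,
            residual=np.zeros(n),
            converged=np.ones(n, dtype=bool),
            merged=np.zeros(n, dtype=bool) if merged is None else merged,
            k2_range=(0.5, 200.0),
        )

    def test_linear_gM_gives_its_slope_as_DM(self):
        tau = np.arange(1, 41, dtype=float)
        fit = self.fit_with(g_M=0.01 * tau, g_mu=np.full(40, 0.004))
        p = extract_parameters(fit)
        assert p.D_M == pytest.approx(0.01, rel=1e-6)
        assert p.plateau_mu == pytest.approx(0.004, rel=1e-6)
        assert p.effective_radius == pytest.approx(2 * np.sqrt(0.004), rel=1e-6)
        assert p.sat_A_M == pytest.approx(0.4, rel=1e-6)
        assert p.sat_A_mu == pytest.approx(0.6, rel=1e-6)

    def test_window_with_too_few_rows_raises(self):
        tau = np.arange(1, 11, dtype=float)
        fit = self.fit_with(g_M=0.01 * tau, g_mu=0.001 * tau)
        fit.converged[:] = False
        with pytest.raises(WindowError):
            extract_parameters(fit)

    def test_invalid_window_bounds(self):
        tau = np.arange(1, 11, dtype=float)
        fit = self.fit_with(g_M=0.01 * tau, g_mu=0.001 * tau)
        with pytest.raises(WindowError):
            extract_parameters(fit, early_window=(8, 20))

    def test_zero_amplitude_rows_excluded_from_slope(self):
        # a row whose macro amplitude vanished carries a garbage exponent;
        # it must not leak into D_M
        tau = np.arange(1, 41, dtype=float)
        g_M = 0.01 * tau
        A_M = np.full(40, 0.4)
        g_M[2] = 1e3
        A_M[2] = 0.0
        fit = self.fit_with(g_M=g_M, g_mu=np.full(40, 0.004), A_M=A_M)
        p = extract_parameters(fit)
        assert p.D_M == pytest.approx(0.01, rel=1e-6)


class TestTwoFreeSpecies:
    def exact_mix(self, D1=0.1, D2=0.01, n1=0.5, n_tau=16):
        k2 = np.linspace(0.5, 60, 30)
        tau = np.arange(n_tau, dtype=float)
        vals = n1 * np.exp(-k2[None, :] * D1 * tau[:, None]) + (1 - n1) * np.exp(
            -k2[None, :] * D2 * tau[:, None]
        )
        return make_cf(vals, k2, tau, normalized=True)

    def test_exact_recovery(self):
        res = fit_two_free_species(self.exact_mix(0.1, 0.01, 0.3))
        assert res.D1 == pytest.approx(0.1, rel=1e-6)
        assert res.D2 == pytest.approx(0.01, rel=1e-6)
        assert res.N1_frac == pytest.approx(0.3, rel=1e-6)
        assert not res.degenerate

    def test_single_species_detected_as_degenerate(self):
        res = fit_two_free_species(self.exact_mix(0.02, 0.02, 0.5))
        assert res.degenerate
        assert res.D1 == pytest.approx(0.02, rel=0.05)

    def test_recovery_from_simulated_mixture(self):
        """A rendered 50/50 mixture of two free populations returns both
        diffusion coefficients (within 15%) and the fraction (within 10%)."""
        import dataclasses

        from ckics import SimulationConfig, compute_kics_cf, crop_center, render_series, simulate

        base = SimulationConfig(
            region_px=128, n_frames=460, burn_in_frames=60, frame_time=0.1,
            area_fraction=0.0, particle_density=2.5, seed=21,
        )
        fast = base.replace(D_out=0.1)
        slow = base.replace(D_out=0.01, seed=22)
        tf, _ = simulate(fast)
        ts, _ = simulate(slow)
        sf = render_series(tf, pixel_size=0.1)
        ss = render_series(ts, pixel_size=0.1)
        mix = crop_center(
            dataclasses.replace(sf, frames=sf.frames + ss.frames), 112
        )
        ncf = compute_kics_cf(mix, max_tau=40, normalize=True)
        res = fit_two_free_species(ncf, k2_range=(0, 100))
        assert not res.degenerate
        assert res.D1 == pytest.approx(0.1, rel=0.15)
        assert res.D2 == pytest.approx(0.01, rel=0.15)
        assert res.N1_frac == pytest.approx(0.5, abs=0.10)

    def test_full_fraction_limit_reduces_to_single_species(self):
        # with all weight on one species the exponents collapse onto its D;
        # the fraction split between two identical decays is then arbitrary
        res = fit_two_free_species(self.exact_mix(0.05, 0.005, 1.0))
        assert res.degenerate
        assert res.D1 == pytest.approx(0.05, rel=1e-3)
        assert res.D2 == pytest.approx(0.05, rel=1e-3)
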