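"""Torsional-spring chain: equipartition map, energy minimization, gamma fit.

The independent oracle for the chain energy is direct numerical minimization
over the internal node angles (scipy), and for the effective stiffness the
series-compliance closed form (sum 1/kappa)^-1.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from tropofil import chain_mechanics as cm
from tropofil import synthetic_md as smd


def brute_force_chain_energy(kappa, theta_rad):
    """Numerical minimization oracle over internal node angles."""
    kappa = np.asarray(kappa, dtype=float)
    n = len(kappa)

    def energy(phi_int):
        phi = np.concatenate(([0.0], phi_int, [theta_rad]))
        return 0.5 * np.sum(kappa * np.diff(phi) ** 2)

    x0 = np.linspace(0, theta_rad, n + 1)[1:-1]
    res = minimize(energy, x0, method="BFGS", options={"gtol": 1e-12, "maxiter": 10_000})
    return res.fun


class TestStiffnessFromFlexibility:
    def test_equipartition_value_at_one_radian(self):
        """delta = 1 rad at 300 K gives kappa = R*T = 2.494 kJ/mol/rad^2."""
        prof = smd.FlexibilityProfile(
            "x", np.arange(1, 6), np.full(5, np.degrees(1.0))
        )
        chain = cm.stiffness_from_flexibility(prof, temperature=300.0)
        assert np.allclose(chain.kappa, 8.314462618e-3 * 300.0)

    def test_uniform_delta_gives_uniform_kappa(self):
        prof = smd.generate_flexibility_profile(2.0, span=30)
        chain = cm.stiffness_from_flexibility(prof)
        assert np.ptp(chain.kappa) == 0.0

    def test_inverse_square_law(self):
        delta = np.full(10, 1.5)
        delta[4] = 3.0  # doubled fluctuation at one node
        prof = smd.FlexibilityProfile("x", np.arange(1, 11), delta)
        chain = cm.stiffness_from_flexibility(prof)
        base = cm.stiffness_from_flexibility(
            smd.FlexibilityProfile("x", np.arange(1, 11), np.full(10, 1.5))
        )
        assert chain.kappa[4] == pytest.approx(base.kappa[4] / 4.0)
        mask = np.arange(10) != 4
        assert np.allclose(chain.kappa[mask], base.kappa[mask])

    def test_zero_delta_rejected(self):
        prof = smd.FlexibilityProfile("x", np.arange(1, 4), np.array([1.0, 1.0, 1.0]))
        object.__setattr__(prof, "delta", np.array([1.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="infinite stiffness"):
            cm.stiffness_from_flexibility(prof)

    def test_invalid_temperature(self):
        prof = smd.generate_flexibility_profile(1.0, span=5)
        with pytest.raises(ValueError, match="temperature"):
            cm.stiffness_from_flexibility(prof, temperature=0.0)


class TestChainEnergyCurve:
    def test_zero_displacement_zero_energy(self):
        chain = cm.TorsionalChain(np.array([1.0, 2.0, 3.0]))
        curve = cm.chain_energy_curve(chain, np.array([0.0, 10.0, 20.0]))
        assert curve.energy[0] == 0.0

    def test_uniform_chain_closed_form(self):
        """Uniform kappa over N segments: E = (1/2)(kappa/N) theta^2."""
        kappa, n = 5.0, 12
        chain = cm.TorsionalChain(np.full(n, kappa))
        grid = np.linspace(0, 35, 8)
        curve = cm.chain_energy_curve(chain, grid)
        expected = 0.5 * (kappa / n) * np.radians(grid) ** 2
        assert np.allclose(curve.energy, expected, rtol=1e-12)

    def test_matches_numerical_minimization_oracle(self, rng):
        kappa = rng.uniform(0.5, 20.0, size=9)
        chain = cm.TorsionalChain(kappa)
        grid = np.array([0.0, 12.0, 27.0, 35.0])
        curve = cm.chain_energy_curve(chain, grid)
        for theta, e in zip(grid[1:], curve.energy[1:]):
            oracle = brute_force_chain_energy(kappa, np.radians(theta))
            assert e == pytest.approx(oracle, rel=1e-6)

    def test_energy_nondecreasing(self, rng):
        chain = cm.TorsionalChain(rng.uniform(0.1, 50.0, size=40))
        curve = cm.chain_energy_curve(chain, np.linspace(0, 35, 36))
        assert np.all(np.diff(curve.energy) >= 0)

    @pytest.mark.parametrize(
        "grid", [[5.0, 10.0], [0.0, 10.0, 40.0], [0.0, 20.0, 10.0]]
    )
    def test_bad_grids_rejected(self, grid):
        chain = cm.TorsionalChain(np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            cm.chain_energy_curve(chain, np.array(grid))


class TestEffectiveStiffnessFit:
    @pytest.mark.parametrize("gamma", [60.0, 31.6])
    def test_round_trip_exact(self, gamma):
        """Noise-free quadratic curves recover the generating stiffness."""
        grid = np.linspace(0, 35, 36)
        curve = cm.ChainEnergyCurve(grid, 0.5 * gamma * np.radians(grid) ** 2)
        fit = cm.fit_effective_stiffness(curve)
        assert fit.gamma == pytest.approx(gamma, rel=1e-12)
        assert fit.residual < 1e-20

    def test_noisy_fit_within_confidence_band(self, rng):
        """Monte-Carlo over noise draws: estimates scatter around truth."""
        gamma = 45.0
        grid = np.linspace(0, 35, 36)
        clean = 0.5 * gamma * np.radians(grid) ** 2
        x = 0.5 * np.radians(grid) ** 2
        sigma = 0.05 * clean.max()
        se = sigma / np.sqrt(np.sum(x**2))  # linear-regression SE of gamma
        fits = np.array(
            [
                cm.fit_effective_stiffness(
                    cm.ChainEnergyCurve(grid, clean + rng.normal(0, sigma, clean.shape))
                ).gamma
                for _ in range(100)
            ]
        )
        assert abs(fits.mean() - gamma) < 3 * se / np.sqrt(100)
        assert fits.std(ddof=1) < 2 * se

    def test_all_zero_energies_rejected(self):
        curve = cm.ChainEnergyCurve(np.array([0.0, 1.0, 2.0]), np.zeros(3))
        with pytest.raises(ValueError, match="undefined"):
            cm.fit_effective_stiffness(curve)

    def test_too_few_points_rejected(self):
        curve = cm.ChainEnergyCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="3 points"):
            cm.fit_effective_stiffness(curve)


class TestSeriesComplianceInvariant:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.05, max_value=200.0), min_size=2, max_size=200),
    )
    def test_fitted_gamma_equals_series_compliance(self, kappas):
        """For any chain the fitted stiffness is (sum 1/kappa)^-1."""
        kappa = np.array(kappas)
        chain = cm.TorsionalChain(kappa)
        curve = cm.chain_energy_curve(chain, np.linspace(0, 35, 12))
        fit = cm.fit_effective_stiffness(curve)
        oracle = 1.0 / np.sum(1.0 / kappa)
        assert abs(fit.gamma - oracle) / oracle < 1e-6

    def test_softening_one_residue_never_raises_gamma(self, wt_baseline_delta):
        base = smd.generate_flexibility_profile(wt_baseline_delta, span=30)
        g0 = cm.series_stiffness(cm.stiffness_from_flexibility(base).kappa)
        for idx in (0, 14, 29):
            delta = base.delta.copy()
            delta[idx] *= 1.5
            softer = smd.FlexibilityProfile("x", base.residues, delta)
            g1 = cm.series_stiffness(cm.stiffness_from_flexibility(softer).kappa)
            assert g1 < g0


class TestMutantCalibration:
    def test_mutant_profile_softer_than_wt(self, wt_baseline_delta):
        """A localized flexibility increase near the mutation site lowers gamma."""
        amp = smd.calibrate_bump_amplitude(31.6, wt_baseline_delta)
        assert amp > 0
        wt = smd.generate_flexibility_profile(wt_baseline_delta)
        mut = smd.generate_flexibility_profile(
            wt_baseline_delta,
            perturbation=smd.Perturbation(smd.DEFAULT_BUMP_CENTER, 5.0, amp),
        )
        fit = lambda p: cm.fit_effective_stiffness(
            cm.chain_energy_curve(
                cm.stiffness_from_flexibility(p), np.linspace(0, 35, 36)
            )
        ).gamma
        g_wt, g_mut = fit(wt), fit(mut)
        assert g_mut < g_wt
        assert g_wt == pytest.approx(60.0, rel=1e-9)
        assert g_mut == pytest.approx(31.6, rel=1e-9)

    def test_target_above_baseline_rejected(self, wt_baseline_delta):
        with pytest.raises(ValueError, match="below"):
            smd.calibrate_bump_amplitude(80.0, wt_baseline_delta)
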