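"""Mie optics: series implementation against closed forms and an
arbitrary-precision oracle."""

import numpy as np
import pytest

from pelkit.mie import (
    MieError,
    ScatteringSpectrum,
    SphereScatterer,
    fit_scattering_power,
    mie_amplitudes,
    mie_cross_sections,
    phase_matrix,
    radius_from_cross_section,
    solve_mie,
)

from oracles import mie_series_oracle


class TestAmplitudes:
    def test_invalid_parameters_raise(self):
        with pytest.raises(MieError):
            SphereScatterer(-1.0)
        with pytest.raises(MieError):
            SphereScatterer(0.0)
        with pytest.raises(MieError):
            SphereScatterer(1.0).size_parameter(-500.0)

    def test_rayleigh_limit_dolp_and_vanishing_amplitudes(self):
        """x -> 0: amplitudes vanish and -m12/m11 at 90 degrees -> 1."""
        s = SphereScatterer(0.002)  # x ~ 0.03
        s1, s2 = mie_amplitudes(s, 550.0, np.array([np.pi / 2]))
        assert abs(s1[0]) < 1e-3 and abs(s2[0]) < 1e-3
        m11, m12, _, _ = phase_matrix(s1, s2)
        assert -m12[0] / m11[0] == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("x", [0.1, 1.0, 5.0, 20.0])
    def test_oracle_equivalence(self, x):
        """Amplitudes and efficiencies match the arbitrary-precision series
        oracle to <1e-8 relative, for the tissue relative index."""
        m = 1.42 / 1.35
        wavelength = 550.0
        radius = x * wavelength * 1e-3 / (2 * np.pi * 1.35)
        s = SphereScatterer(radius)
        assert s.size_parameter(wavelength) == pytest.approx(x, rel=1e-12)
        angles = np.linspace(0.0, np.pi, 19)
        s1, s2 = mie_amplitudes(s, wavelength, angles)
        o_s1, o_s2, o_qsca, o_qext, o_g = mie_series_oracle(x, m, angles)
        scale = np.abs(o_s2).max()
        np.testing.assert_allclose(s1, o_s1, rtol=1e-8, atol=1e-8 * scale)
        np.testing.assert_allclose(s2, o_s2, rtol=1e-8, atol=1e-8 * scale)
        sigma_sca, sigma_ext, g = mie_cross_sections(s, wavelength)
        geo = np.pi * radius**2
        assert sigma_sca / geo == pytest.approx(o_qsca, rel=1e-8)
        assert sigma_ext / geo == pytest.approx(o_qext, rel=1e-8)
        assert g == pytest.approx(o_g, rel=1e-8, abs=1e-10)

    def test_forward_scattering_amplitudes_equal(self):
        s = SphereScatterer(0.8)
        s1, s2 = mie_amplitudes(s, 550.0, np.array([0.0]))
        assert s1[0] == pytest.approx(s2[0], rel=1e-12)


class TestCrossSections:
    def test_optical_theorem_nonabsorbing(self):
        """Real relative index: sigma_ext == sigma_sca to 1e-10 relative."""
        for radius in (0.1, 0.6, 1.3):
            ss, se, _ = mie_cross_sections(SphereScatterer(radius), 550.0)
            assert se == pytest.approx(ss, rel=1e-10)

    def test_rayleigh_asymmetry_near_zero(self):
        _, _, g = mie_cross_sections(SphereScatterer(0.002), 550.0)
        assert abs(g) < 1e-3

    def test_cross_section_matches_phase_function_quadrature(self):
        """sigma_sca equals 2*pi/k^2 * int m11 sin(theta) dtheta."""
        s = SphereScatterer(0.7)
        sol = solve_mie(s, 550.0)
        k = 2 * np.pi * s.n_medium / 0.55  # um^-1
        quad = 2 * np.pi * np.trapezoid(sol.m11 * np.sin(sol.angles), sol.angles) / k**2
        assert quad == pytest.approx(sol.sigma_sca, rel=1e-4)


class TestPhaseMatrix:
    def test_forward_m12_zero(self):
        sol = solve_mie(SphereScatterer(0.9), 550.0)
        assert sol.m12[0] == pytest.approx(0.0, abs=1e-9 * sol.m11[0])

    @pytest.mark.parametrize("radius", [0.05, 0.5, 1.2])
    def test_cauchy_schwarz_bounds(self, radius):
        """m11 >= |m12| and m11 >= |m34| at every angle."""
        sol = solve_mie(SphereScatterer(radius), 480.0)
        assert np.all(sol.m11 >= np.abs(sol.m12) - 1e-12 * sol.m11.max())
        assert np.all(sol.m11 >= np.abs(sol.m34) - 1e-12 * sol.m11.max())
        assert np.all(sol.m11 >= 0)

    def test_elements_match_oracle(self):
        """x=3, m=1.05: all four elements match the series oracle per angle."""
        m_rel = 1.05
        wavelength = 550.0
        radius = 3.0 * wavelength * 1e-3 / (2 * np.pi * 1.35)
        s = SphereScatterer(radius, n_particle=m_rel * 1.35)
        angles = np.linspace(0.0, np.pi, 13)
        s1, s2 = mie_amplitudes(s, wavelength, angles)
        o_s1, o_s2, *_ = mie_series_oracle(3.0, m_rel, angles)
        for ours, oracle in zip(phase_matrix(s1, s2), phase_matrix(o_s1, o_s2)):
            np.testing.assert_allclose(ours, oracle, rtol=1e-7, atol=1e-12)

    def test_normalized_m11_integrates_to_one(self):
        sol = solve_mie(SphereScatterer(1.0), 550.0)
        p = sol.normalized_m11()
        integral = 2 * np.pi * np.trapezoid(p * np.sin(sol.angles), sol.angles)
        assert integral == pytest.approx(1.0, abs=1e-4)


class TestRadiusInversion:
    def test_round_trip(self):
        radius = radius_from_cross_section(0.5)
        sigma, _, _ = mie_cross_sections(SphereScatterer(radius), 550.0)
        assert sigma == pytest.approx(0.5, abs=1e-6)

    def test_against_grid_scan(self):
        """Inverse agrees with a dense brute-force scan over radius."""
        target = 0.5
        radii = np.linspace(0.05, 1.5, 2000)
        sig = np.array([mie_cross_sections(SphereScatterer(r), 550.0)[0] for r in radii])
        best = radii[np.argmin(np.abs(sig - target))]
        assert radius_from_cross_section(target) == pytest.approx(best, abs=1e-3)

    def test_negative_target_raises(self):
        with pytest.raises(MieError):
            radius_from_cross_section(-1.0)

    def test_unattainable_target_names_range(self):
        with pytest.raises(MieError, match="attainable"):
            radius_from_cross_section(1e6)


class TestScatteringPower:
    def test_exact_power_law_recovered(self):
        lam = np.linspace(350, 750, 40)
        spec = ScatteringSpectrum(lam, 3.7 * lam**-1.2)
        assert fit_scattering_power(spec).b == pytest.approx(1.2, abs=1e-12)

    def test_constant_spectrum_gives_zero(self):
        lam = np.linspace(350, 750, 10)
        assert fit_scattering_power(ScatteringSpectrum(lam, np.full(10, 5.0))).b == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        lam = np.linspace(350, 750, 30)
        musp = 2.0 * lam**-0.8 * (1 + 0.05 * np.sin(lam / 40))
        b1 = fit_scattering_power(ScatteringSpectrum(lam, musp)).b
        b2 = fit_scattering_power(ScatteringSpectrum(lam, 17.3 * musp)).b
        assert b1 == pytest.approx(b2, rel=1e-12)

    def test_matches_independent_regression_on_mie_spectrum(self):
        from oracles import ols_normal_equations

        radius = radius_from_cross_section(0.5)
        lam = np.linspace(350, 750, 21)
        sig = np.array([mie_cross_sections(SphereScatterer(radius), l)[0] for l in lam])
        ours = fit_scattering_power(ScatteringSpectrum(lam, sig)).b
        beta = ols_normal_equations(np.log(lam)[:, None], np.log(sig))
        assert ours == pytest.approx(-beta[1], rel=1e-10)

    def test_nonpositive_values_raise(self):
        lam = np.linspace(350, 750, 5)
        with pytest.raises(MieError):
            fit_scattering_power(ScatteringSpectrum(lam, np.array([1, 2, 0, 3, 4.0])))
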