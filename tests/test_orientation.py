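"""Harmonic inversion of polarization stacks: phases, rho, Kleinman fit."""

import numpy as np
import pytest

from conftest import ANGLES18, circ_diff, render_pixel_stack
from shgpol.model import coeffs_from_rho, nonkleinman_intensity
from shgpol.orientation import (FourierCoeffMap, OrientationResult,
                                PolarizationStack, combine_phi, estimate_rho,
                                fit_orientation, fourier_coefficients,
                                kleinman_fit, validity_mask, wrap_axial)

THETA18 = np.deg2rad(ANGLES18)


def lsq_harmonic_fit(intensities, theta):
    """Independent oracle: linear least squares in the trigonometric basis
    {1, cos2t, sin2t, cos4t, sin4t}, orientation from the 2nd harmonic."""
    X = np.column_stack([np.ones_like(theta), np.cos(2 * theta),
                         np.sin(2 * theta), np.cos(4 * theta),
                         np.sin(4 * theta)])
    b = np.linalg.lstsq(X, intensities, rcond=None)[0]
    phi = 0.5 * np.arctan2(b[2], b[1])
    return b[0], np.hypot(b[1], b[2]), np.hypot(b[3], b[4]), wrap_axial(phi)


def stack_from_harmonics(a0, a2, a4, phi, angles_deg=ANGLES18):
    theta = np.deg2rad(angles_deg)
    frames = (a0 + a2 * np.cos(2 * (theta - phi))
              + a4 * np.cos(4 * (theta - phi)))[None, None, :]
    return PolarizationStack(frames, angles_deg)


class TestStackValidation:
    def test_rejects_bad_angle_grids(self):
        frames = np.ones((2, 2, 17))
        with pytest.raises(ValueError):
            PolarizationStack(frames, np.arange(17) * 10.0)
        with pytest.raises(ValueError):
            PolarizationStack(np.ones((2, 2, 18)), np.arange(18) * 9.5)
        with pytest.raises(ValueError):
            PolarizationStack(-np.ones((2, 2, 18)), ANGLES18)

    def test_repeat_averaging(self):
        raw = np.stack([np.full((18, 4, 4), v) for v in (0.0, 3.0, 6.0)],
                       axis=1)
        st = PolarizationStack.from_repeats(raw, ANGLES18)
        assert st.repeats == 3
        np.testing.assert_allclose(st.frames, 3.0)


class TestFourierCoefficients:
    def test_constant_stack(self):
        st = PolarizationStack(np.full((2, 3, 18), 5.0), ANGLES18)
        c = fourier_coefficients(st)
        np.testing.assert_allclose(c.alpha0, 5.0)
        np.testing.assert_allclose(c.alpha2, 0.0, atol=1e-12)
        np.testing.assert_allclose(c.alpha4, 0.0, atol=1e-12)

    def test_known_harmonics_recovered(self):
        phi = np.deg2rad(20.0)
        st = stack_from_harmonics(2.0, 1.0, 0.25, phi)
        c = fourier_coefficients(st)
        assert c.alpha0[0, 0] == pytest.approx(2.0, abs=1e-12)
        assert c.alpha2[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert c.alpha4[0, 0] == pytest.approx(0.25, abs=1e-12)
        assert np.degrees(c.phi2[0, 0]) == pytest.approx(20.0, abs=1e-9)
        # cross-check against the linear least-squares oracle
        a0, a2m, a4m, phi_lsq = lsq_harmonic_fit(st.frames[0, 0], THETA18)
        assert a0 == pytest.approx(2.0, abs=1e-10)
        assert np.degrees(phi_lsq) == pytest.approx(20.0, abs=1e-7)

    def test_rho_coefficient_magnitudes(self):
        st = render_pixel_stack(0.0, 1.5, 1.0)
        c = fourier_coefficients(st)
        assert c.alpha2[0, 0] == pytest.approx(0.625, abs=1e-12)
        assert c.alpha4[0, 0] == pytest.approx(0.46875, abs=1e-12)


class TestCombinePhi:
    def test_beta_one_returns_phi2(self):
        one = np.ones((1, 1))
        c = FourierCoeffMap(alpha0=one * 2, alpha2=one, alpha4=one * 0,
                            phi2=one * 0.3, phi4=one * 0.0, beta=one,
                            c1=one * np.exp(-2j * 0.3), c2=one * 0j)
        phi, m = combine_phi(c)
        assert phi[0, 0] == pytest.approx(0.3)

    def test_beta_zero_lifts_phi4_branch(self):
        # true orientation 80 deg: phi4 = -10 deg, branch m = 2
        one = np.ones((1, 1))
        c = FourierCoeffMap(alpha0=one * 2, alpha2=one * 0, alpha4=one,
                            phi2=one * np.deg2rad(80.0),
                            phi4=one * np.deg2rad(-10.0), beta=one * 0.0,
                            c1=one * 0j, c2=one + 0j)
        phi, m = combine_phi(c)
        assert m[0, 0] == 2
        assert np.degrees(phi[0, 0]) == pytest.approx(80.0)

    def test_no_modulation_is_undefined(self):
        st = PolarizationStack(np.full((1, 1, 18), 5.0), ANGLES18)
        phi, _ = combine_phi(fourier_coefficients(st))
        assert np.isnan(phi[0, 0])

    @pytest.mark.parametrize("phi_deg", [-80, -45, -10, 0, 10, 45, 80])
    def test_matches_grid_search_oracle(self, phi_deg):
        """Combined estimate equals a 0.001-deg grid search of the residual."""
        st = render_pixel_stack(np.deg2rad(phi_deg), 1.5)
        phi, _ = combine_phi(fourier_coefficients(st))
        grid = np.deg2rad(np.arange(-90.0, 90.0, 0.001))
        c = coeffs_from_rho(1.5, 1.0)
        model = (c.a0 + c.a2 * np.cos(2 * (THETA18[None] - grid[:, None]))
                 + c.a4 * np.cos(4 * (THETA18[None] - grid[:, None])))
        best = grid[np.argmin(((model - st.frames[0, 0]) ** 2).sum(axis=1))]
        assert abs(np.degrees(circ_diff(phi[0, 0], best))) < 1e-3
        assert abs(np.degrees(circ_diff(phi[0, 0], np.deg2rad(phi_deg)))) < 1e-6


class TestEstimateRho:
    @pytest.mark.parametrize("rho", [-0.5, 0.5, 1.2, 1.5, 2.0, 2.9])
    def test_round_trip_through_coeffs(self, rho):
        phi = np.deg2rad(25.0)
        c = coeffs_from_rho(rho, 1.0)
        one = np.ones((1, 1))
        cm = FourierCoeffMap(
            alpha0=one * c.a0, alpha2=one * abs(c.a2), alpha4=one * abs(c.a4),
            phi2=one * phi, phi4=one * phi, beta=one,
            c1=one * c.a2 * np.exp(-2j * phi),
            c2=one * c.a4 * np.exp(-4j * phi))
        got = estimate_rho(cm, one * phi)
        assert got[0, 0] == pytest.approx(rho, abs=1e-9)

    def test_a4_zero_gives_rho_three(self):
        one = np.ones((1, 1))
        cm = FourierCoeffMap(alpha0=one * 5, alpha2=one * 4, alpha4=one * 0,
                             phi2=one * 0, phi4=one * 0, beta=one,
                             c1=one * 4 + 0j, c2=one * 0j)
        assert estimate_rho(cm, one * 0.0)[0, 0] == pytest.approx(3.0)

    def test_singular_ratio_is_invalid(self):
        # r = a4/a2 = 0.25 makes the inversion denominator vanish
        one = np.ones((1, 1))
        cm = FourierCoeffMap(alpha0=one * 5, alpha2=one * 4, alpha4=one * 1,
                             phi2=one * 0, phi4=one * 0, beta=one,
                             c1=one * 4 + 0j, c2=one * 1 + 0j)
        assert np.isnan(estimate_rho(cm, one * 0.0)[0, 0])


class TestExactRecovery:
    def test_noiseless_grid(self):
        """Noiseless stacks invert exactly over the physical (phi, rho) grid."""
        for phi_deg in (-80, -45, -10, 0, 10, 45, 80):
            for rho in (1.1, 1.5, 2.0, 2.5, 2.9):
                st = render_pixel_stack(np.deg2rad(phi_deg), rho, K=3.0)
                res = fit_orientation(st, intensity_floor=0.1)
                assert abs(circ_diff(res.phi[0, 0],
                                     np.deg2rad(phi_deg))) < 1e-6
                assert abs(res.rho[0, 0] - rho) < 1e-9

    def test_noise_monotonicity(self):
        """Orientation RMSE falls as the photon budget grows."""
        from shgpol.simulate import generate_field, render_pstack

        truth = generate_field("adult", (64, 64), seed=11)
        rmses = []
        for photons in (1e2, 1e3, 1e4):
            errs = []
            for rep in range(3):
                st = render_pstack(truth, photons=photons,
                                   seed=100 * rep + int(photons))
                res = fit_orientation(st, intensity_floor=0.0)
                d = circ_diff(res.phi, truth.phi)
                errs.append(np.sqrt(np.nanmean(d**2)))
            rmses.append(np.mean(errs))
        assert rmses[0] > rmses[1] > rmses[2]


class TestKleinmanFit:
    def _pixel_stack(self, K, A, B, phi):
        frames = nonkleinman_intensity(THETA18, phi, K, A, B)[None, None, :]
        return PolarizationStack(frames, ANGLES18)

    def _init(self, st):
        return fit_orientation(st, intensity_floor=0.1)

    def test_recovers_kleinman_pixel(self):
        st = self._pixel_stack(100.0, 1.0, 1.5, np.deg2rad(30.0))
        fit = kleinman_fit(st, self._init(st))
        assert fit.valid[0, 0]
        assert fit.A[0, 0] == pytest.approx(1.0, abs=1e-4)
        assert fit.rho[0, 0] == pytest.approx(1.5, abs=1e-4)
        assert np.degrees(fit.phi[0, 0]) == pytest.approx(30.0, abs=1e-4)

    def test_matches_independent_grid_refinement(self):
        """Batched LM agrees with a coarse (A, B, phi) grid search refined
        by scipy's reference optimizer on the same residual."""
        from scipy.optimize import least_squares

        st = self._pixel_stack(80.0, 0.97, 1.7, np.deg2rad(-40.0))
        data = st.frames[0, 0]
        grid = [(a, b, p) for a in np.linspace(0.8, 1.2, 9)
                for b in np.linspace(1.0, 2.5, 16)
                for p in np.deg2rad(np.arange(-90, 90, 5.0))]
        costs = [np.sum((nonkleinman_intensity(THETA18, p, 80.0, a, b)
                         - data) ** 2) for a, b, p in grid]
        a0, b0, p0 = grid[int(np.argmin(costs))]
        ref = least_squares(
            lambda q: nonkleinman_intensity(THETA18, q[3], q[0], q[1], q[2])
            - data, x0=[80.0, a0, b0, p0], xtol=1e-14, ftol=1e-14)
        fit = kleinman_fit(st, self._init(st))
        assert fit.A[0, 0] == pytest.approx(abs(ref.x[1]), abs=1e-4)
        assert abs(circ_diff(fit.phi[0, 0], ref.x[3])) < 1e-5

    def test_violating_pixel_is_flagged(self):
        st = self._pixel_stack(100.0, 1.3, 1.5, np.deg2rad(30.0))
        fit = kleinman_fit(st, self._init(st))
        assert abs(fit.A[0, 0]) >= 1.1
        assert not fit.valid[0, 0]

    def test_constant_pixel_is_degenerate(self):
        st = PolarizationStack(np.full((1, 1, 18), 7.0), ANGLES18)
        fit = kleinman_fit(st, self._init(st))
        assert not fit.valid[0, 0]

    def test_filter_robustness_near_kleinman(self):
        """phi maps with and without the filter agree (median < 2 deg) when
        A varies in [0.95, 1.05], as for real collagen."""
        rng = np.random.default_rng(5)
        n = 40
        A = rng.uniform(0.95, 1.05, (n, n))
        B = rng.uniform(1.3, 2.0, (n, n))
        phi = rng.uniform(-np.pi / 2, np.pi / 2, (n, n))
        lam = nonkleinman_intensity(THETA18[:, None, None], phi[None], 200.0,
                                    A[None], B[None])
        frames = rng.poisson(lam).astype(float)
        st = PolarizationStack(np.moveaxis(frames, 0, -1), ANGLES18)
        no_filter = fit_orientation(st, intensity_floor=1.0)
        with_filter = kleinman_fit(st, no_filter)
        assert with_filter.valid.mean() > 0.9
        d = np.abs(np.degrees(circ_diff(with_filter.phi, no_filter.phi)))
        assert np.nanmedian(d) < 2.0


class TestValidityMask:
    def test_signal_and_residual_gates(self):
        st = render_pixel_stack(0.3, 1.5, K=1.0)  # alpha0 ~ 2.09
        c = fourier_coefficients(st)
        assert validity_mask(st, c, intensity_floor=1.0)[0, 0]
        dark = PolarizationStack(np.zeros((1, 1, 18)), ANGLES18)
        cd = fourier_coefficients(dark)
        assert not validity_mask(dark, cd, intensity_floor=1.0)[0, 0]

    def test_pure_noise_rejected(self):
        """Structureless noise fails the residual gate in >=99% of 1000
        seeded replicates."""
        rng = np.random.default_rng(42)
        frames = rng.exponential(5.0, (1000, 1, 18))
        st = PolarizationStack(frames, ANGLES18)
        mask = validity_mask(st, fourier_coefficients(st),
                             intensity_floor=1.0, residual_ceiling=0.3)
        assert mask.mean() <= 0.01
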