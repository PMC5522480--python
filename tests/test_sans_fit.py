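"""Power-law, single-curve and joint contrast fitting; SLD regression."""

import numpy as np
import pytest

from helixsans.sans_fit import (
    fit_contrast_series,
    fit_powerlaw_exponent,
    fit_single_curve,
    water_fraction_from_slds,
)
from helixsans.sans_model import (
    SANSCurve,
    SANSModelParams,
    composite_intensity,
    solvent_sld,
)
from helixsans.synthetic_data import (
    default_q_grid,
    simulate_contrast_series,
)


def powerlaw_curve(amplitude, exponent, noise=0.0, seed=0):
    q = np.geomspace(0.004, 0.05, 60)
    intensity = amplitude * q ** (-exponent)
    sigma = np.maximum(noise * intensity, 1e-12)
    if noise > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(scale=sigma)
    return SANSCurve(q=q, intensity=intensity, sigma=sigma)


class TestPowerlaw:
    def test_exact_power_law_recovered(self):
        n, se = fit_powerlaw_exponent(powerlaw_curve(1e-6, 3.6))
        assert n == pytest.approx(3.600, abs=1e-9)

    @pytest.mark.parametrize("exponent", [3.5, 3.6, 3.7])
    def test_one_percent_noise_within_band(self, exponent):
        errs = [
            abs(fit_powerlaw_exponent(
                powerlaw_curve(1e-6, exponent, noise=0.01, seed=s)
            )[0] - exponent)
            for s in range(10)
        ]
        assert np.median(errs) < 0.05

    def test_flat_curve_warns(self):
        q = np.geomspace(0.004, 0.05, 30)
        flat = SANSCurve(q=q, intensity=np.full_like(q, 0.01),
                         sigma=np.full_like(q, 1e-4))
        with pytest.warns(UserWarning, match="outside the surface-scattering"):
            n, _ = fit_powerlaw_exponent(flat)
        assert abs(n) < 0.5

    def test_too_few_points_rejected(self):
        curve = powerlaw_curve(1e-6, 3.6)
        with pytest.raises(ValueError, match="at least 4"):
            fit_powerlaw_exponent(curve, q_window=(0.0001, 0.0002))

    def test_non_positive_intensity_rejected(self):
        q = np.geomspace(0.006, 0.017, 10)
        curve = SANSCurve(q=q, intensity=np.linspace(1.0, -0.1, 10),
                          sigma=np.ones(10))
        with pytest.raises(ValueError, match="non-positive"):
            fit_powerlaw_exponent(curve)


def noiseless_curve(params, rel_sigma=0.01, n_q=60):
    q = default_q_grid(n_q)
    intensity = composite_intensity(q, params)
    return SANSCurve(q=q, intensity=intensity, sigma=rel_sigma * intensity,
                     d2o_fraction=params.d2o_fraction)


TRUE_SINGLE = SANSModelParams(
    radius_a=13.0, length_a=75.0, sld_particle=4.2,
    sld_solvent=solvent_sld(1.0), volfraction=0.005, charge=20.0,
    screening_length_a=30.0, powerlaw_amplitude=2e-6,
    powerlaw_exponent=3.6, background=1e-3, d2o_fraction=1.0,
)


class TestSingleCurveFit:
    def test_recovers_geometry_from_perturbed_init(self):
        curve = noiseless_curve(TRUE_SINGLE)
        init = SANSModelParams(
            **{**TRUE_SINGLE.__dict__, "radius_a": 13.0 * 1.2,
               "length_a": 75.0 * 0.8, "sld_particle": 4.2 * 1.1}
        )
        res = fit_single_curve(curve, init, n_starts=3)
        assert res.converged
        assert res.params["radius_a"] == pytest.approx(13.0, rel=0.01)
        assert res.params["length_a"] == pytest.approx(75.0, rel=0.01)

    def test_monte_carlo_radius_recovery(self):
        """2 % noise: median relative radius error stays below 5 %."""
        rng_errors = []
        for seed in range(8):
            q = default_q_grid(50)
            intensity = composite_intensity(q, TRUE_SINGLE)
            sigma = 0.02 * intensity
            noisy = intensity + np.random.default_rng(seed).normal(
                scale=sigma
            )
            curve = SANSCurve(q=q, intensity=noisy, sigma=sigma,
                              d2o_fraction=1.0)
            init = SANSModelParams(
                **{**TRUE_SINGLE.__dict__, "radius_a": 15.0, "length_a": 60.0}
            )
            res = fit_single_curve(curve, init, n_starts=2)
            rng_errors.append(abs(res.params["radius_a"] - 13.0) / 13.0)
        assert np.median(rng_errors) < 0.05

    def test_background_only_fit_is_weighted_mean(self):
        q = np.geomspace(0.01, 0.3, 30)
        rng = np.random.default_rng(5)
        intensity = 0.002 + rng.normal(scale=1e-4, size=q.size)
        sigma = np.full_like(q, 1e-4)
        curve = SANSCurve(q=q, intensity=intensity, sigma=sigma)
        init = SANSModelParams(
            radius_a=13.0, length_a=75.0, sld_particle=solvent_sld(1.0),
            sld_solvent=solvent_sld(1.0), volfraction=0.005,
            powerlaw_amplitude=0.0, background=0.001,
        )
        fixed = {
            "radius_a", "length_a", "sld_particle", "volfraction", "charge",
            "screening_length_a", "powerlaw_amplitude", "powerlaw_exponent",
            "scale",
        }
        res = fit_single_curve(curve, init, fixed=fixed, n_starts=1)
        wmean = np.sum(intensity / sigma**2) / np.sum(1.0 / sigma**2)
        assert res.params["background"] == pytest.approx(wmean, rel=1e-6)

    def test_unknown_fixed_name_rejected(self):
        curve = noiseless_curve(TRUE_SINGLE)
        with pytest.raises(ValueError, match="unknown parameter"):
            fit_single_curve(curve, TRUE_SINGLE, fixed={"bogus"})


class TestContrastSeriesFit:
    def test_noiseless_recovery_and_chi2_consistency(self):
        series = simulate_contrast_series("pH2", relative_noise=0.0, seed=0)
        # noiseless sigma is zero -> unit weights, warned once per curve
        init = SANSModelParams(
            radius_a=15.0, length_a=60.0, sld_particle=3.0,
            sld_solvent=solvent_sld(1.0), volfraction=0.005, charge=20.0,
            screening_length_a=30.0, powerlaw_amplitude=1e-6,
            powerlaw_exponent=3.55, background=2e-3,
        )
        with pytest.warns(UserWarning, match="unit weights"):
            res = fit_contrast_series(series, init, n_starts=3)
        assert res.converged
        assert res.params["radius_a"] == pytest.approx(13.0, rel=0.01)
        assert res.params["length_a"] == pytest.approx(75.0, rel=0.01)
        # truly shared parameters: the joint fit reaches (near) zero misfit,
        # so its chi2 cannot exceed the summed single-curve optima by more
        # than numerical slack
        with pytest.warns(UserWarning, match="unit weights"):
            singles = sum(
                fit_single_curve(c, init, n_starts=2).chi2 for c in series
            )
        assert res.chi2 <= singles + 1e-4

    def test_single_curve_rejected(self):
        from helixsans.sans_model import ContrastSeries

        series = simulate_contrast_series("pH2", relative_noise=0.0, seed=0)
        solo = ContrastSeries(curves=[series.curves[0]])
        init = SANSModelParams(
            radius_a=13.0, length_a=75.0, sld_particle=3.0,
            sld_solvent=solvent_sld(1.0),
        )
        with pytest.raises(ValueError, match="at least 2"):
            fit_contrast_series(solo, init)

    def test_duplicate_fractions_rejected(self):
        from helixsans.sans_model import ContrastSeries

        series = simulate_contrast_series("pH2", relative_noise=0.0, seed=0)
        dup = ContrastSeries(curves=[series.curves[0], series.curves[0]])
        init = SANSModelParams(
            radius_a=13.0, length_a=75.0, sld_particle=3.0,
            sld_solvent=solvent_sld(1.0),
        )
        with pytest.raises(ValueError, match="distinct"):
            fit_contrast_series(dup, init)


class TestWaterFraction:
    def test_exact_line_slope_51_percent(self):
        solvents = np.array([solvent_sld(f) for f in (1.0, 0.75, 0.5)])
        particles = 0.51 * solvents + (1 - 0.51) * 2.0
        res = water_fraction_from_slds(particles, solvents)
        assert res.phi_water == pytest.approx(0.51, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.sld_dry == pytest.approx(2.0, abs=1e-9)
        assert not res.clipped

    def test_dry_particle_zero_slope(self):
        solvents = np.array([6.0, 3.0, 1.0])
        particles = np.full(3, 2.0)
        res = water_fraction_from_slds(particles, solvents)
        assert res.phi_water == 0.0

    def test_two_points_exact_interpolation_warns(self):
        with pytest.warns(UserWarning, match="two-point"):
            res = water_fraction_from_slds([4.0, 2.0], [6.0, 2.0])
        assert res.r_squared == pytest.approx(1.0)
        assert res.n_points == 2

    def test_identical_solvents_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            water_fraction_from_slds([4.0, 2.0], [6.0, 6.0])

    def test_noisy_slope_outside_unit_interval_is_clipped(self):
        solvents = np.array([6.0, 3.0, 0.0])
        particles = 1.2 * solvents + 0.5  # unphysical slope > 1
        res = water_fraction_from_slds(particles, solvents)
        assert res.clipped
        assert res.phi_water == 1.0
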