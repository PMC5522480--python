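"""Generators: geometry, determinism, planted statistical structure."""

import numpy as np
import pytest

from helixsans.helix_geometry import fit_helix, rmsd_to_ideal_helix
from helixsans.peptide_model import build_topology
from helixsans.sans_model import SANSModelParams, composite_intensity, solvent_sld
from helixsans.synthetic_data import (
    Frame,
    default_q_grid,
    generate_ideal_helix,
    generate_random_coil,
    generate_trajectory,
    perturb_conformation,
    read_sans_curve,
    read_trajectory_pdb,
    simulate_contrast_series,
    simulate_sans_curve,
    simulate_titration,
    solvate,
    write_sans_curve,
    write_trajectory_pdb,
)


class TestIdealHelix:
    def test_calpha_exactly_on_cylinder(self):
        conf = generate_ideal_helix(10, 0.23, 100.0, 0.15)
        ca = conf.calpha()
        # generator builds around the z axis
        assert np.allclose(np.hypot(ca[:, 0], ca[:, 1]), 0.23, atol=1e-12)

    def test_two_point_projection_angle(self):
        conf = generate_ideal_helix(2, 0.23, 100.0, 0.15)
        ca = conf.calpha()
        v0, v1 = ca[0][:2], ca[1][:2]
        ang = np.degrees(
            np.arccos(v0 @ v1 / np.linalg.norm(v0) / np.linalg.norm(v1))
        )
        assert ang == pytest.approx(100.0, abs=1e-9)

    def test_axial_separation_closed_form(self):
        # residues 1 and 19 (1-based) sit 18 rises apart
        ca = generate_ideal_helix(36, 0.23, 100.0, 0.15).calpha()
        assert ca[18, 2] - ca[0, 2] == pytest.approx(18 * 0.15, abs=1e-12)

    def test_bonded_distances_physical(self, helix10):
        """Every bonded pair (backbone chain + side-chain ladder) sits
        within 0.05-0.25 nm."""
        m = helix10.model
        c = helix10.coords

        def d(r, a, r2, b):
            return np.linalg.norm(c[m.atom(r, a).index] - c[m.atom(r2, b).index])

        for r in range(m.n_residues):
            assert 0.05 < d(r, "N", r, "CA") < 0.25
            assert 0.05 < d(r, "N", r, "H") < 0.25
            assert 0.05 < d(r, "CA", r, "C") < 0.25
            assert 0.05 < d(r, "C", r, "O") < 0.25
            assert 0.05 < d(r, "CA", r, "L1") < 0.25
            assert 0.05 < d(r, "L1", r, "L2") < 0.25
            assert 0.05 < d(r, "L4", r, "NT") < 0.25

    @pytest.mark.parametrize(
        "kwargs", [dict(radius=-0.1), dict(twist=0.0), dict(twist=185.0),
                   dict(rise=0.0)]
    )
    def test_non_physical_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_ideal_helix(10, **{"radius": 0.23, "twist": 100.0,
                                        "rise": 0.15, **kwargs})


class TestRandomCoil:
    def test_seed_determinism(self):
        a = generate_random_coil(10, 1)
        b = generate_random_coil(10, 1)
        assert np.array_equal(a.coords, b.coords)

    def test_self_avoidance(self):
        ca = generate_random_coil(50, 7).calpha()
        d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
        iu = np.triu_indices(50, k=2)  # non-bonded pairs
        assert d[iu].min() >= 0.4

    def test_fixed_step_length(self):
        ca = generate_random_coil(30, 11).calpha()
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.allclose(steps, 0.38, atol=1e-9)

    def test_coil_is_far_from_helical(self):
        ca = generate_random_coil(50, 7).calpha()
        assert rmsd_to_ideal_helix(ca) > 0.2


class TestPerturb:
    def test_zero_amplitude_identity(self, helix10):
        out = perturb_conformation(helix10, 0.0, seed=5)
        assert np.array_equal(out.coords, helix10.coords)

    def test_small_noise_rmsd_band(self, helix10):
        rmsds = [
            rmsd_to_ideal_helix(
                perturb_conformation(helix10, 0.02, seed=s).calpha()
            )
            for s in range(50)
        ]
        med = np.median(rmsds)
        assert 0.0 < med <= 0.06

    def test_coil_stays_non_helical(self, coil10):
        fit = fit_helix(perturb_conformation(coil10, 0.02, seed=1).calpha())
        assert abs(fit.radius_nm - 0.23) > 0.1 or fit.rmsd_helix_nm > 0.2

    def test_negative_amplitude_rejected(self, helix10):
        with pytest.raises(ValueError):
            perturb_conformation(helix10, -0.1, seed=0)


class TestSolvate:
    def test_planted_depletion_sphere_is_empty(self, helix10):
        frame = solvate(helix10, 6.0, 1500, depletion_radius=0.4, seed=2)
        com = np.full(3, 3.0)  # backbone COM moved to the box centre
        d = frame.water_o - com
        d -= 6.0 * np.round(d / 6.0)
        assert np.linalg.norm(d, axis=1).min() >= 0.4

    def test_zero_depletion_lets_water_approach(self, helix10):
        frame = solvate(helix10, 6.0, 10000, depletion_radius=0.0, seed=2,
                        clash_distance=0.0)
        com = np.full(3, 3.0)
        d = np.linalg.norm(frame.water_o - com, axis=1)
        assert d.min() < 0.35

    def test_dry_frame_is_valid(self, helix10):
        frame = solvate(helix10, 6.0, 0, seed=0)
        assert frame.n_waters == 0

    def test_box_smaller_than_peptide_rejected(self, helix10):
        with pytest.raises(ValueError, match="box edge"):
            solvate(helix10, 1.0, 10, seed=0)

    def test_waters_carry_two_rigid_hydrogens(self, helix10):
        frame = solvate(helix10, 6.0, 200, seed=4)
        oh = np.linalg.norm(
            frame.water_h - frame.water_o[:, None, :], axis=-1
        )
        assert np.allclose(oh, 0.1, atol=1e-9)


class TestTrajectory:
    def test_stable_helix_stays_helical(self, model10_protonated):
        traj = generate_trajectory(
            model10_protonated, "stable_helix", 20, 0.1, seed=9
        )
        rmsds = [
            rmsd_to_ideal_helix(f.conformation.calpha()) for f in traj
        ]
        assert max(rmsds) <= 0.08

    def test_folding_is_monotone_in_expectation(self, model10_protonated):
        traj = generate_trajectory(
            model10_protonated, "folding", 100, 1.0, seed=5
        )
        rmsds = np.array(
            [rmsd_to_ideal_helix(f.conformation.calpha()) for f in traj]
        )
        assert rmsds[-10:].mean() < rmsds[:10].mean()

    def test_single_frame_accepted(self, model10):
        traj = generate_trajectory(model10, "stable_coil", 1, 0.1, seed=0)
        assert len(traj) == 1

    def test_unknown_kind_rejected(self, model10):
        with pytest.raises(ValueError, match="unknown trajectory kind"):
            generate_trajectory(model10, "unfolding", 5, 0.1, seed=0)

    def test_bit_reproducible(self, model10):
        a = generate_trajectory(model10, "folding", 5, 0.1, seed=3,
                                n_waters=50)
        b = generate_trajectory(model10, "folding", 5, 0.1, seed=3,
                                n_waters=50)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.conformation.coords, fb.conformation.coords)
            assert np.array_equal(fa.water_o, fb.water_o)
            assert np.array_equal(fa.water_h, fb.water_h)


class TestSANSCurves:
    def test_noiseless_curve_equals_forward_model(self):
        params = SANSModelParams(
            radius_a=13.0, length_a=75.0, sld_particle=4.0,
            sld_solvent=solvent_sld(1.0), background=1e-3,
        )
        q = default_q_grid(40)
        curve = simulate_sans_curve(params, q, relative_noise=0.0, seed=0)
        assert np.array_equal(curve.intensity, composite_intensity(q, params))
        assert np.all(curve.sigma == 0.0)

    def test_default_grid_spans_instrument_range(self):
        q = default_q_grid()
        assert q[0] == pytest.approx(0.0057)
        assert q[-1] == pytest.approx(0.32)

    def test_same_seed_same_noise(self):
        params = SANSModelParams(
            radius_a=13.0, length_a=75.0, sld_particle=4.0,
            sld_solvent=solvent_sld(1.0),
        )
        a = simulate_sans_curve(params, relative_noise=0.05, seed=42)
        b = simulate_sans_curve(params, relative_noise=0.05, seed=42)
        assert np.array_equal(a.intensity, b.intensity)

    def test_bad_q_grid_rejected(self):
        params = SANSModelParams(
            radius_a=13.0, length_a=75.0, sld_particle=4.0,
            sld_solvent=solvent_sld(1.0),
        )
        with pytest.raises(ValueError):
            simulate_sans_curve(params, np.array([0.1, 0.05]), 0.0, 0)


class TestContrastSeries:
    def test_three_contrasts_share_q_grid(self):
        series = simulate_contrast_series("pH2", relative_noise=0.0, seed=0)
        assert len(series) == 3
        q0 = series.curves[0].q
        for c in series:
            assert np.array_equal(c.q, q0)
        assert series.d2o_fractions == [1.0, 0.75, 0.5]

    def test_fully_hydrated_particle_is_contrast_matched(self):
        """phi_water = 1: particle SLD equals solvent SLD at every
        contrast, so only power law + background remain."""
        series = simulate_contrast_series(
            dict(radius_a=13.0, length_a=75.0, powerlaw_amplitude=0.0,
                 background=2e-3),
            phi_water=1.0, relative_noise=0.0, seed=0,
        )
        for c in series:
            assert np.allclose(c.intensity, 2e-3, atol=1e-12)

    def test_dry_particle_sld_constant_across_contrasts(self):
        from helixsans.sans_model import particle_sld

        slds = [
            particle_sld(0.0, 2.0, solvent_sld(f)) for f in (1.0, 0.75, 0.5)
        ]
        assert len(set(slds)) == 1

    def test_empty_contrast_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_contrast_series("pH2", d2o_fractions=[], seed=0)

    def test_presets_encode_the_two_states(self):
        from helixsans.synthetic_data import contrast_preset

        acid = contrast_preset("pH2")
        base = contrast_preset("pH8")
        assert acid["radius_a"] == base["radius_a"] == 13.0
        assert acid["length_a"] > base["length_a"]
        assert acid["phi_water"] < base["phi_water"]


class TestTitration:
    def test_midpoint_identity(self):
        t = simulate_titration(4.1, np.array([4.1]), 0.0, 0)
        assert t.fraction[0] == pytest.approx(0.5, abs=1e-12)

    def test_neutral_ph_fraction_closed_form(self):
        t = simulate_titration(4.1, np.array([7.0]), 0.0, 0)
        assert t.fraction[0] == pytest.approx(1 / (1 + 10**2.9), rel=1e-9)

    def test_noiseless_curve_monotone_decreasing(self):
        t = simulate_titration(4.1, np.linspace(1, 10, 50), 0.0, 0)
        assert np.all(np.diff(t.fraction) < 0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate_titration(4.1, np.array([]), 0.0, 0)


class TestIO:
    def test_pdb_round_trip(self, model10, tmp_path):
        traj = generate_trajectory(model10, "stable_coil", 3, 0.1, seed=8,
                                   n_waters=30)
        path = str(tmp_path / "traj.pdb")
        write_trajectory_pdb(traj, path)
        back = read_trajectory_pdb(path, model10, time_step_ns=0.1)
        assert len(back) == 3
        for fa, fb in zip(traj, back):
            # PDB stores 3 decimals in Angstrom -> 1e-4 nm precision
            assert np.allclose(fa.conformation.coords,
                               fb.conformation.coords, atol=2e-4)
            assert np.allclose(fa.water_o, fb.water_o, atol=2e-4)
            assert fb.box_edge == pytest.approx(6.0, abs=1e-3)

    def test_sans_ascii_round_trip(self, tmp_path):
        params = SANSModelParams(
            radius_a=13.0, length_a=75.0, sld_particle=4.0,
            sld_solvent=solvent_sld(0.75), d2o_fraction=0.75,
        )
        curve = simulate_sans_curve(params, relative_noise=0.02, seed=1)
        path = str(tmp_path / "curve.dat")
        write_sans_curve(curve, path)
        back = read_sans_curve(path)
        assert back.d2o_fraction == 0.75
        assert np.allclose(back.q, curve.q)
        assert np.allclose(back.intensity, curve.intensity)
        assert np.allclose(back.sigma, curve.sigma)
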