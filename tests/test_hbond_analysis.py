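"""H-bond detection, classification, partition and chain-end accounting."""

import numpy as np
import pytest

from helixsans.hbond_analysis import (
    classify_hbond,
    count_dangling_backbone_groups,
    detect_hbonds,
    per_residue_hbond_stats,
)
from helixsans.peptide_model import build_topology
from helixsans.synthetic_data import (
    Conformation,
    Frame,
    Trajectory,
    generate_ideal_helix,
    generate_random_coil,
    solvate,
    _extend_linear,
    _full_coords_from_ca,
)
from tests.conftest import single_frame_trajectory, vacuum_frame


def brute_force_bonds(frame, model, dist_cutoff=0.35, angle_cutoff=30.0):
    """Independent O(n^2) enumeration of every donor-H/acceptor pair with
    the same closest-acceptor-wins rule (oracle for the KD-tree path)."""
    n_pep = model.n_atoms
    coords = [frame.conformation.coords[i] for i in range(n_pep)]
    donors = list(model.donor_sites())
    acceptors = list(model.acceptor_sites())
    for w in range(frame.n_waters):
        o = n_pep + 3 * w
        coords.extend([frame.water_o[w], frame.water_h[w, 0], frame.water_h[w, 1]])
        donors += [(o, o + 1, "water"), (o, o + 2, "water")]
        acceptors.append((o, "water"))
    coords = np.asarray(coords)
    box = frame.box_edge

    def mi(v):
        return v - box * np.round(v / box)

    def molecule(i):
        return -1 if i < n_pep else (i - n_pep) // 3

    def residue(i):
        return model.atoms[i].residue if i < n_pep else -1

    def backbone(i):
        return i < n_pep and model.atoms[i].group == "backbone"

    def excluded(d, a):
        if a == d:
            return True
        if molecule(a) == molecule(d) and molecule(d) >= 0:
            return True  # one water molecule
        if residue(d) >= 0 and residue(d) == residue(a):
            return True  # one peptide residue
        return (
            backbone(d)
            and backbone(a)
            and abs(residue(d) - residue(a)) == 1
        )  # bonded backbone neighbours

    out = []
    for d, h, dgrp in donors:
        best = None
        for a, agrp in acceptors:
            if excluded(d, a):
                continue
            v_da = mi(coords[a] - coords[d])
            dist = np.linalg.norm(v_da)
            if dist > dist_cutoff:
                continue
            v_dh = mi(coords[h] - coords[d])
            ang = np.degrees(
                np.arccos(
                    np.clip(
                        v_da @ v_dh / (dist * np.linalg.norm(v_dh)), -1, 1
                    )
                )
            )
            if ang > angle_cutoff:
                continue
            key = (dist, a)
            if best is None or key < best[0]:
                best = (key, (d, h, a, dgrp, agrp))
        if best is not None:
            out.append(best[1])
    return out


def place_probe_water(model, conf, donor_res, distance):
    """Water O on the N->H axis of one backbone amide at the given
    donor-acceptor distance (collinear: angle 0)."""
    n = conf.coords[model.atom(donor_res, "N").index]
    h = conf.coords[model.atom(donor_res, "H").index]
    u = (h - n) / np.linalg.norm(h - n)
    o = n + distance * u
    hs = np.array([[o + [0.1, 0, 0], o + [0, 0.1, 0]]])
    return Frame(conf, o[None, :], hs, box_edge=1e6)


class TestDetection:
    def test_collinear_pair_inside_cutoffs_detected(self, model10, coil10):
        frame = place_probe_water(model10, coil10, donor_res=5, distance=0.29)
        bonds = detect_hbonds(frame, model10)
        probe = [b for b in bonds if b.acceptor == model10.n_atoms]
        assert len(probe) == 1
        assert probe[0].hb_class == "BW"
        assert probe[0].distance_nm == pytest.approx(0.29, abs=1e-9)
        assert probe[0].angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_distance_beyond_default_cutoff_rejected(self, model10, coil10):
        frame = place_probe_water(model10, coil10, donor_res=5, distance=0.40)
        bonds = detect_hbonds(frame, model10)
        assert not any(b.acceptor == model10.n_atoms for b in bonds)

    def test_angle_beyond_cutoff_rejected(self, model10, coil10):
        frame = place_probe_water(model10, coil10, donor_res=5, distance=0.29)
        # rotate the probe O by ~45 deg about the donor N
        n = coil10.coords[model10.atom(5, "N").index]
        h = coil10.coords[model10.atom(5, "H").index]
        u = (h - n) / np.linalg.norm(h - n)
        p = np.array([1.0, 0, 0]) - u[0] * u
        p /= np.linalg.norm(p)
        o = n + 0.29 * (np.cos(np.radians(45)) * u + np.sin(np.radians(45)) * p)
        frame.water_o[0] = o
        bonds = detect_hbonds(frame, model10)
        assert not any(
            b.acceptor == model10.n_atoms and b.donor == model10.atom(5, "N").index
            for b in bonds
        )

    def test_ideal_helix_has_exactly_n_minus_4_backbone_bonds(self):
        for n in (5, 7, 10, 12):
            model = build_topology(n, "triazole", protonated=True)
            frame = vacuum_frame(generate_ideal_helix(n, model=model))
            bb = [b for b in detect_hbonds(frame, model) if b.hb_class == "BB"]
            assert len(bb) == n - 4

    def test_agrees_with_brute_force_oracle(self, model10, helix10):
        frame = solvate(helix10, 6.0, 120, seed=13)
        fast = {
            (b.donor, b.hydrogen, b.acceptor)
            for b in detect_hbonds(frame, helix10.model)
        }
        slow = {(d, h, a) for d, h, a, _, _ in
                brute_force_bonds(frame, helix10.model)}
        assert fast == slow

    def test_triazolium_nitrogen_never_accepts(self, model10_protonated):
        conf = generate_ideal_helix(10, model=model10_protonated)
        frame = solvate(conf, 6.0, 2000, seed=21)
        n3_ids = {
            model10_protonated.atom(r, "N3").index for r in range(10)
        }
        bonds = detect_hbonds(frame, model10_protonated)
        assert not any(b.acceptor in n3_ids for b in bonds)

    def test_mismatched_frame_rejected(self, model10, model10_protonated):
        conf = generate_ideal_helix(10, model=model10_protonated)
        with pytest.raises(ValueError, match="does not match"):
            detect_hbonds(vacuum_frame(conf), model10)

    def test_partition_is_exhaustive_and_disjoint(self, model10, coil10):
        frame = solvate(coil10, 6.0, 800, seed=17)
        bonds = detect_hbonds(frame, model10)
        by_class = {c: sum(b.hb_class == c for b in bonds)
                    for c in ("BB", "BW", "BS", "other")}
        assert sum(by_class.values()) == len(bonds)


class TestClassification:
    def test_backbone_to_backbone(self, model10_protonated, helix10):
        bonds = detect_hbonds(vacuum_frame(helix10), model10_protonated)
        assert bonds and all(b.hb_class == "BB" for b in bonds)
        for b in bonds:
            assert classify_hbond(b, model10_protonated) == "BB"

    def test_backbone_to_water(self, model10, coil10):
        frame = place_probe_water(model10, coil10, 5, 0.29)
        b = [x for x in detect_hbonds(frame, model10)
             if x.acceptor == model10.n_atoms][0]
        assert classify_hbond(b, model10, n_waters=1) == "BW"

    def test_unresolvable_atom_id_rejected(self, model10):
        from helixsans.hbond_analysis import HBond

        bogus = HBond(donor=10**6, hydrogen=0, acceptor=0,
                      distance_nm=0.3, angle_deg=0.0, hb_class="other")
        with pytest.raises(KeyError):
            classify_hbond(bogus, model10, n_waters=1)


class TestPerResidueStats:
    def test_ideal_helix_bb_per_residue(self, model10_protonated, helix10):
        stats = per_residue_hbond_stats(
            single_frame_trajectory(vacuum_frame(helix10)),
            model10_protonated,
            n_exclude=0,
        )
        assert stats.mean["BB"] == pytest.approx(0.6)  # 6 bonds / 10 residues
        assert stats.std["BB"] == 0.0

    def test_chain_end_exclusion_drops_bonds_and_denominator(
        self, model10_protonated, helix10
    ):
        # included residues 2..7: only the i->i+4 ladder rungs 6->2 and
        # 7->3 survive; 2 bonds over 6 residues
        stats = per_residue_hbond_stats(
            single_frame_trajectory(vacuum_frame(helix10)),
            model10_protonated,
            n_exclude=2,
        )
        assert stats.n_included_residues == 6
        assert stats.mean["BB"] == pytest.approx(2 / 6)

    def test_densely_solvated_coil_is_water_dominated(self, model10):
        coil = generate_random_coil(10, seed=3, model=model10)
        frame = solvate(coil, 6.0, 5000, seed=5)
        stats = per_residue_hbond_stats(
            single_frame_trajectory(frame), model10, n_exclude=0
        )
        assert stats.mean["BW"] > 0.9

    def test_vacuum_has_no_water_or_sidechain_acceptor_bonds(
        self, model10_protonated, helix10
    ):
        stats = per_residue_hbond_stats(
            single_frame_trajectory(vacuum_frame(helix10)),
            model10_protonated,
            n_exclude=0,
        )
        assert stats.mean["BW"] == 0.0
        assert stats.mean["BS"] == 0.0

    def test_over_exclusion_rejected(self, model10, coil10):
        traj = single_frame_trajectory(vacuum_frame(coil10))
        with pytest.raises(ValueError, match="no residues"):
            per_residue_hbond_stats(traj, model10, n_exclude=5)


class TestDanglingGroups:
    def test_ideal_ten_mer_has_four_free_groups_per_end(
        self, model10_protonated, helix10
    ):
        assert count_dangling_backbone_groups(
            helix10, model10_protonated
        ) == (4, 4)

    def test_five_mer_single_rung(self):
        model = build_topology(5, "triazole", protonated=True)
        helix = generate_ideal_helix(5, model=model)
        frame = vacuum_frame(helix)
        bb = [b for b in detect_hbonds(frame, model) if b.hb_class == "BB"]
        assert len(bb) == 1
        assert count_dangling_backbone_groups(helix, model) == (4, 4)

    def test_extended_chain_every_group_free(self, model10):
        ca = np.c_[np.zeros(10), np.zeros(10), 0.38 * np.arange(10)]
        conf = Conformation(
            _full_coords_from_ca(model10, _extend_linear(ca)), model10
        )
        assert count_dangling_backbone_groups(conf, model10) == (10, 10)
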