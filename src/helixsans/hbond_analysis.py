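"""Geometric hydrogen-bond detection and the three-way partition into
backbone-backbone (B-B), backbone-water (B-W) and backbone-side-chain (B-S)
bonds, with chain-end accounting.

Criterion: donor-acceptor distance <= 0.35 nm and H-donor-acceptor angle
<= 30 deg (the conventional MD-analysis default; the source system reports
counts but no criterion, so both cutoffs are exposed). A donor hydrogen
joins at most one bond per frame - the closest eligible acceptor wins, ties
broken by lower atom id - which prevents double counting in dense water.
Covalently connected pairs (within one water, within one residue, or
backbone atoms of adjacent residues) are never counted, the usual bonded
exclusion of MD H-bond analyses.

Donor/acceptor eligibility comes from the ligand table in
:mod:`helixsans.peptide_model`: a triazolium N3 is never an acceptor, an
ester carbonyl only accepts.

Atom ids: peptide atoms keep their topology indices; water atoms continue
the numbering as O, H1, H2 per molecule in order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peptide_model import PeptideModel
from .synthetic_data import Conformation, Frame, Trajectory

__all__ = [
    "HBond",
    "HBondStats",
    "detect_hbonds",
    "classify_hbond",
    "per_residue_hbond_stats",
    "count_dangling_backbone_groups",
    "DEFAULT_DIST_CUTOFF_NM",
    "DEFAULT_ANGLE_CUTOFF_DEG",
]

DEFAULT_DIST_CUTOFF_NM = 0.35
DEFAULT_ANGLE_CUTOFF_DEG = 30.0

CLASSES = ("BB", "BW", "BS", "other")


@dataclass(frozen=True)
class HBond:
    donor: int          # donor heavy-atom id
    hydrogen: int
    acceptor: int
    distance_nm: float  # donor-acceptor distance
    angle_deg: float    # hydrogen-donor-acceptor angle
    hb_class: str       # BB | BW | BS | other


@dataclass
class HBondStats:
    """Per-class H-bonds per included residue, averaged over frames."""

    mean: dict[str, float]
    std: dict[str, float]
    per_frame: pd.DataFrame   # integer bond counts per class, one row/frame
    n_included_residues: int


class _SiteTable:
    """Flat donor/acceptor site arrays for one frame (peptide + water)."""

    def __init__(self, frame: Frame, model: PeptideModel):
        if frame.conformation.model is not model:
            if frame.conformation.model.n_atoms != model.n_atoms:
                raise ValueError("frame does not match the peptide model")
        n_pep = model.n_atoms
        n_w = frame.n_waters
        coords = np.empty((n_pep + 3 * n_w, 3))
        coords[:n_pep] = frame.conformation.coords
        if n_w:
            w = np.empty((n_w, 3, 3))
            w[:, 0] = frame.water_o
            w[:, 1:] = frame.water_h
            coords[n_pep:] = w.reshape(-1, 3)
        self.coords = coords
        self.box = frame.box_edge

        don, hyd, dgrp = [], [], []
        for d, h, grp in model.donor_sites():
            don.append(d)
            hyd.append(h)
            dgrp.append(grp)
        acc, agrp = [], []
        for a, grp in model.acceptor_sites():
            acc.append(a)
            agrp.append(grp)
        for wmol in range(n_w):
            o = n_pep + 3 * wmol
            don.extend([o, o])
            hyd.extend([o + 1, o + 2])
            dgrp.extend(["water", "water"])
            acc.append(o)
            agrp.append("water")
        self.donor = np.array(don, dtype=int)
        self.hydrogen = np.array(hyd, dtype=int)
        self.donor_group = np.array(dgrp)
        self.acceptor = np.array(acc, dtype=int)
        self.acceptor_group = np.array(agrp)
        # residue id per atom (peptide) / molecule id (water), for
        # excluding intra-molecular "bonds" within one water
        self.molecule = np.empty(n_pep + 3 * n_w, dtype=int)
        # peptide residue per atom (-1 for water) and backbone flags, for
        # the covalent-neighbour exclusion
        self.residue = np.full(n_pep + 3 * n_w, -1, dtype=int)
        self.backbone = np.zeros(n_pep + 3 * n_w, dtype=bool)
        for a in model.atoms:
            self.molecule[a.index] = -1  # peptide: one molecule
            self.residue[a.index] = a.residue
            self.backbone[a.index] = a.group == "backbone"
        for wmol in range(n_w):
            self.molecule[n_pep + 3 * wmol : n_pep + 3 * wmol + 3] = wmol

    def covalently_linked(self, d: np.ndarray, a: np.ndarray) -> np.ndarray:
        """Pairs connected through a few covalent bonds, never H-bond
        partners: atoms of one water molecule, atoms of one peptide
        residue, and backbone atoms of adjacent residues (the amide N and
        the preceding carbonyl are directly bonded)."""
        same_water = (self.molecule[d] == self.molecule[a]) & (
            self.molecule[d] >= 0
        )
        both_peptide = (self.residue[d] >= 0) & (self.residue[a] >= 0)
        same_residue = both_peptide & (self.residue[d] == self.residue[a])
        adjacent_backbone = (
            both_peptide
            & self.backbone[d]
            & self.backbone[a]
            & (np.abs(self.residue[d] - self.residue[a]) == 1)
        )
        return same_water | same_residue | adjacent_backbone


def _min_image_vec(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def detect_hbonds(
    frame: Frame,
    model: PeptideModel,
    dist_cutoff: float = DEFAULT_DIST_CUTOFF_NM,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF_DEG,
) -> list[HBond]:
    """All hydrogen bonds in one frame under the geometric criterion,
    one bond at most per donor hydrogen (closest acceptor wins).

    Candidate pairs come from a periodic KD-tree on the acceptor
    positions, so dense solvated frames stay fast.
    """
    from scipy.spatial import cKDTree

    if dist_cutoff <= 0 or angle_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    t = _SiteTable(frame, model)
    if t.donor.size == 0 or t.acceptor.size == 0:
        return []
    dpos = t.coords[t.donor]
    apos = t.coords[t.acceptor]
    hpos = t.coords[t.hydrogen]
    box = t.box
    tree = cKDTree(np.mod(apos, box), boxsize=box)
    neigh = tree.query_ball_point(np.mod(dpos, box), r=dist_cutoff)
    lens = np.fromiter((len(x) for x in neigh), dtype=int, count=len(neigh))
    if lens.sum() == 0:
        return []
    di = np.repeat(np.arange(len(neigh)), lens)
    aj = np.concatenate([np.asarray(x, dtype=int) for x in neigh if x])

    # drop self pairs and covalently connected pairs
    keep = (t.donor[di] != t.acceptor[aj]) & ~t.covalently_linked(
        t.donor[di], t.acceptor[aj]
    )
    di, aj = di[keep], aj[keep]
    if di.size == 0:
        return []
    v_da = _min_image_vec(apos[aj] - dpos[di], box)
    dist = np.linalg.norm(v_da, axis=1)
    v_dh = _min_image_vec(hpos - dpos, box)[di]
    cosang = np.sum(v_da * v_dh, axis=1) / (
        dist * np.linalg.norm(v_dh, axis=1) + 1e-300
    )
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    keep = (dist <= dist_cutoff) & (ang <= angle_cutoff)
    di, aj, dist, ang = di[keep], aj[keep], dist[keep], ang[keep]
    if di.size == 0:
        return []
    # best acceptor per donor hydrogen: closest, tie -> lowest atom id
    order = np.lexsort((t.acceptor[aj], dist, di))
    first = np.ones(order.size, dtype=bool)
    first[1:] = di[order][1:] != di[order][:-1]
    sel = order[first]
    return [
        HBond(
            donor=int(t.donor[i]),
            hydrogen=int(t.hydrogen[i]),
            acceptor=int(t.acceptor[j]),
            distance_nm=float(d),
            angle_deg=float(a),
            hb_class=_classify(t.donor_group[i], t.acceptor_group[j]),
        )
        for i, j, d, a in zip(di[sel], aj[sel], dist[sel], ang[sel])
    ]


def _classify(donor_group: str, acceptor_group: str) -> str:
    groups = {donor_group, acceptor_group}
    if groups == {"backbone"}:
        return "BB"
    if groups == {"backbone", "water"}:
        return "BW"
    if groups == {"backbone", "sidechain"}:
        return "BS"
    return "other"


def classify_hbond(bond: HBond, model: PeptideModel, n_waters: int = 0) -> str:
    """Class label of a bond from its partner atom ids (BB/BW/BS/other)."""

    def group_of(idx: int) -> str:
        if idx < model.n_atoms:
            return model.atoms[idx].group.replace("ammonium", "sidechain")
        if idx < model.n_atoms + 3 * n_waters or n_waters == 0:
            return "water"
        raise KeyError(f"atom id {idx} not resolvable")

    return _classify(group_of(bond.donor), group_of(bond.acceptor))


def per_residue_hbond_stats(
    traj: Trajectory,
    model: PeptideModel,
    n_exclude: int = 0,
    dist_cutoff: float = DEFAULT_DIST_CUTOFF_NM,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF_DEG,
) -> HBondStats:
    """Mean and standard deviation over frames of H-bonds per included
    residue, per class. Bonds touching an excluded terminal residue are
    dropped, and excluded residues leave the denominator."""
    n_inc = model.n_residues - 2 * n_exclude
    if n_inc < 1:
        raise ValueError("n_exclude leaves no residues")
    included = range(n_exclude, model.n_residues - n_exclude)
    inc_set = set(included)

    rows = []
    for frame in traj:
        counts = dict.fromkeys(CLASSES, 0)
        for bond in detect_hbonds(frame, model, dist_cutoff, angle_cutoff):
            if not _bond_included(bond, model, inc_set):
                continue
            counts[bond.hb_class] += 1
        rows.append(counts)
    per_frame = pd.DataFrame(rows, columns=list(CLASSES))
    per_res = per_frame / n_inc
    return HBondStats(
        mean={c: float(per_res[c].mean()) for c in CLASSES},
        std={c: float(per_res[c].std(ddof=0)) for c in CLASSES},
        per_frame=per_frame,
        n_included_residues=n_inc,
    )


def _bond_included(bond: HBond, model: PeptideModel, inc: set[int]) -> bool:
    """Keep a bond only if every peptide partner is an included residue."""
    for idx in (bond.donor, bond.acceptor):
        if idx < model.n_atoms and model.atoms[idx].residue not in inc:
            return False
    return True


def count_dangling_backbone_groups(
    conf: Conformation,
    model: PeptideModel,
    dist_cutoff: float = DEFAULT_DIST_CUTOFF_NM,
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF_DEG,
) -> tuple[int, int]:
    """(free backbone N-H, free backbone C=O): groups participating in no
    intra-backbone (B-B) bond under the geometric criterion. On a helix
    these sit at the N- and C-terminal ends respectively."""
    frame = Frame(conf, np.empty((0, 3)), np.empty((0, 2, 3)), box_edge=1e6)
    bonds = detect_hbonds(frame, model, dist_cutoff, angle_cutoff)
    bonded_donor_res = set()
    bonded_acceptor_res = set()
    for b in bonds:
        if b.hb_class != "BB":
            continue
        bonded_donor_res.add(model.atoms[b.donor].residue)
        bonded_acceptor_res.add(model.atoms[b.acceptor].residue)
    free_nh = model.n_residues - len(bonded_donor_res)
    free_co = model.n_residues - len(bonded_acceptor_res)
    return free_nh, free_co
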