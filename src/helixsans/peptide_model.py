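"""Topology, protonation state and donor/acceptor bookkeeping for model
cationic polypeptides.

The polypeptides modelled here carry, on every residue, a long flexible
side-chain ending in a quaternary trimethylammonium (+1 e, pH independent)
with an optional hydrogen-bonding ligand part-way along the chain: an amide,
an ester, a 1,2,3-triazole, or its N3-protonated 1,2,3-triazolium form.
The ligand's role in hydrogen bonding is what the analyses downstream care
about:

* binary pattern (BHB)  - the group both donates and accepts (amide,
  neutral triazole via C5-H / N3, water);
* unitary pattern (UHB) - donor-only (triazolium: N3-H and C5-H, the
  protonated N3 can no longer accept) or acceptor-only (ester carbonyl).

Atoms beyond the backbone, the ligand donor/acceptor sites and the terminal
ammonium are represented as linker pseudo-atoms: the geometry analyses only
need backbone atoms, H-bond sites, charges and excluded volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

__all__ = [
    "LigandKind",
    "HBPattern",
    "HBondRole",
    "AtomSite",
    "PeptideModel",
    "ChargeLedger",
    "hbond_pattern",
    "build_topology",
    "net_formal_charge",
]

# atomic masses (u) for the elements the model uses
ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

BACKBONE_ATOM_NAMES = ("N", "H", "CA", "C", "O")


class LigandKind(str, Enum):
    """Closed set of side-chain H-bonding ligand labels."""

    AMIDE = "amide"
    ESTER = "ester"
    TRIAZOLE = "triazole"
    TRIAZOLIUM = "triazolium"
    TRIMETHYLAMMONIUM = "trimethylammonium"
    WATER = "water"

    @classmethod
    def coerce(cls, value: "LigandKind | str") -> "LigandKind":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"unknown ligand kind {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


class HBPattern(str, Enum):
    UHB_DONOR = "UHB_donor"
    UHB_ACCEPTOR = "UHB_acceptor"
    BHB = "BHB"
    NONE = "none"


@dataclass(frozen=True)
class HBondRole:
    """Donor/acceptor site counts of a functional group and the derived
    unitary/binary classification."""

    donors: int
    acceptors: int

    @property
    def pattern(self) -> HBPattern:
        if self.donors >= 1 and self.acceptors >= 1:
            return HBPattern.BHB
        if self.donors >= 1:
            return HBPattern.UHB_DONOR
        if self.acceptors >= 1:
            return HBPattern.UHB_ACCEPTOR
        return HBPattern.NONE


#: Fixed donor/acceptor table. Amide: N-H donor, C=O acceptor. Ester:
#: carbonyl acceptor only. Triazole: C5-H donor, N3 acceptor. Triazolium:
#: N3-H and C5-H donors, no acceptor. Trimethylammonium: neither. Water:
#: two O-H donors, O acceptor.
_HBOND_TABLE: dict[LigandKind, HBondRole] = {
    LigandKind.AMIDE: HBondRole(donors=1, acceptors=1),
    LigandKind.ESTER: HBondRole(donors=0, acceptors=1),
    LigandKind.TRIAZOLE: HBondRole(donors=1, acceptors=1),
    LigandKind.TRIAZOLIUM: HBondRole(donors=2, acceptors=0),
    LigandKind.TRIMETHYLAMMONIUM: HBondRole(donors=0, acceptors=0),
    LigandKind.WATER: HBondRole(donors=2, acceptors=1),
}


def hbond_pattern(ligand: LigandKind | str) -> HBondRole:
    """Donor/acceptor role of a ligand kind (fixed table lookup)."""
    return _HBOND_TABLE[LigandKind.coerce(ligand)]


@dataclass(frozen=True)
class AtomSite:
    """One atom (or linker pseudo-atom) in the topology."""

    index: int            # global, unique, equals position in coordinate array
    name: str             # unique within its residue
    residue: int          # 0-based residue index
    element: str          # H/C/N/O; pseudo-atoms are carbon-like
    group: str            # 'backbone' | 'sidechain' | 'ammonium'
    charge: int = 0       # formal charge (e)

    @property
    def mass(self) -> float:
        return ATOMIC_MASS[self.element]


# side-chain atom layouts per ligand kind: (name, element, group, charge)
# ordering matters: the synthetic generator and PDB writer follow it.
_SIDECHAIN_LAYOUT: dict[LigandKind, tuple[tuple[str, str, str, int], ...]] = {
    LigandKind.TRIAZOLE: (
        ("L1", "C", "sidechain", 0),
        ("L2", "C", "sidechain", 0),
        ("C5", "C", "sidechain", 0),
        ("H5", "H", "sidechain", 0),
        ("N3", "N", "sidechain", 0),
        ("L3", "C", "sidechain", 0),
        ("L4", "C", "sidechain", 0),
        ("NT", "N", "ammonium", 1),
    ),
    LigandKind.TRIAZOLIUM: (
        ("L1", "C", "sidechain", 0),
        ("L2", "C", "sidechain", 0),
        ("C5", "C", "sidechain", 0),
        ("H5", "H", "sidechain", 0),
        ("N3", "N", "sidechain", 1),
        ("H3", "H", "sidechain", 0),
        ("L3", "C", "sidechain", 0),
        ("L4", "C", "sidechain", 0),
        ("NT", "N", "ammonium", 1),
    ),
    LigandKind.AMIDE: (
        ("L1", "C", "sidechain", 0),
        ("L2", "C", "sidechain", 0),
        ("CS", "C", "sidechain", 0),
        ("OS", "O", "sidechain", 0),
        ("NS", "N", "sidechain", 0),
        ("HS", "H", "sidechain", 0),
        ("L3", "C", "sidechain", 0),
        ("L4", "C", "sidechain", 0),
        ("NT", "N", "ammonium", 1),
    ),
    LigandKind.ESTER: (
        ("L1", "C", "sidechain", 0),
        ("L2", "C", "sidechain", 0),
        ("CS", "C", "sidechain", 0),
        ("OS", "O", "sidechain", 0),
        ("L3", "C", "sidechain", 0),
        ("L4", "C", "sidechain", 0),
        ("NT", "N", "ammonium", 1),
    ),
    LigandKind.TRIMETHYLAMMONIUM: (
        ("L1", "C", "sidechain", 0),
        ("L2", "C", "sidechain", 0),
        ("L3", "C", "sidechain", 0),
        ("L4", "C", "sidechain", 0),
        ("NT", "N", "ammonium", 1),
    ),
}

# ligand donor sites as (donor_name, hydrogen_name) and acceptor site names
_SIDECHAIN_DONORS: dict[LigandKind, tuple[tuple[str, str], ...]] = {
    LigandKind.TRIAZOLE: (("C5", "H5"),),
    LigandKind.TRIAZOLIUM: (("N3", "H3"), ("C5", "H5")),
    LigandKind.AMIDE: (("NS", "HS"),),
    LigandKind.ESTER: (),
    LigandKind.TRIMETHYLAMMONIUM: (),
}
_SIDECHAIN_ACCEPTORS: dict[LigandKind, tuple[str, ...]] = {
    LigandKind.TRIAZOLE: ("N3",),
    LigandKind.TRIAZOLIUM: (),      # protonated N3 never accepts
    LigandKind.AMIDE: ("OS",),
    LigandKind.ESTER: ("OS",),
    LigandKind.TRIMETHYLAMMONIUM: (),
}


@dataclass
class PeptideModel:
    """Topology of one model polypeptide chain.

    ``atoms`` is an ordered list; its order defines the 1:1 mapping onto
    coordinate arrays in :mod:`helixsans.synthetic_data`. Prepared as a
    zwitterion: the N-terminal amine carries +1 and the C-terminal
    carboxylate -1; they cancel in the net charge.
    """

    n_residues: int
    base_ligand: LigandKind
    protonation: tuple[bool, ...]
    atoms: list[AtomSite] = field(repr=False)
    zwitterion: bool = True

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("a chain needs at least 2 residues")
        if len(self.protonation) != self.n_residues:
            raise ValueError("protonation vector length must equal n_residues")
        seen = set()
        for a in self.atoms:
            key = (a.residue, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom identifier {key}")
            seen.add(key)
        self._by_key = {(a.residue, a.name): a for a in self.atoms}

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_ligand(self, residue: int) -> LigandKind:
        if self.base_ligand in (LigandKind.TRIAZOLE, LigandKind.TRIAZOLIUM):
            return (
                LigandKind.TRIAZOLIUM
                if self.protonation[residue]
                else LigandKind.TRIAZOLE
            )
        return self.base_ligand

    def atom(self, residue: int, name: str) -> AtomSite:
        try:
            return self._by_key[(residue, name)]
        except KeyError:
            raise KeyError(f"no atom {name!r} in residue {residue}") from None

    def backbone_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.group == "backbone"]

    def masses(self) -> list[float]:
        return [a.mass for a in self.atoms]

    # ---- H-bond site enumeration -------------------------------------
    def donor_sites(self) -> list[tuple[int, int, str]]:
        """(donor_index, hydrogen_index, group) triples.

        Backbone amide N-H of every residue counts as a donor (the
        N-terminal amine's proton included); side-chain sites follow the
        ligand's donor table.
        """
        out: list[tuple[int, int, str]] = []
        for r in range(self.n_residues):
            out.append((self.atom(r, "N").index, self.atom(r, "H").index, "backbone"))
            for dn, hn in _SIDECHAIN_DONORS[self.residue_ligand(r)]:
                out.append((self.atom(r, dn).index, self.atom(r, hn).index, "sidechain"))
        return out

    def acceptor_sites(self) -> list[tuple[int, str]]:
        """(acceptor_index, group) pairs: backbone carbonyl O of every
        residue plus the ligand's acceptor sites."""
        out: list[tuple[int, str]] = []
        for r in range(self.n_residues):
            out.append((self.atom(r, "O").index, "backbone"))
            for an in _SIDECHAIN_ACCEPTORS[self.residue_ligand(r)]:
                out.append((self.atom(r, an).index, "sidechain"))
        return out

    # ---- serialization ------------------------------------------------
    def to_config(self) -> dict:
        return {
            "n_residues": self.n_residues,
            "ligand": self.base_ligand.value,
            "protonation": [bool(p) for p in self.protonation],
            "zwitterion": self.zwitterion,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "PeptideModel":
        ligand = LigandKind.coerce(cfg["ligand"])
        prot = cfg.get("protonation")
        model = build_topology(
            int(cfg["n_residues"]), ligand, protonated=False
        )
        if prot is not None:
            return set_protonation(model, [bool(p) for p in prot])
        return model


@dataclass(frozen=True)
class ChargeLedger:
    """Per-residue formal charges and their sum."""

    per_residue: tuple[int, ...]
    termini: int  # net contribution of the zwitterionic termini (0)

    @property
    def net(self) -> int:
        return sum(self.per_residue) + self.termini


# ----------------------------------------------------------------------
def build_topology(
    n_residues: int,
    ligand: LigandKind | str,
    protonated: bool = False,
) -> PeptideModel:
    """Construct the topology of an ``n_residues``-mer with one side-chain
    per residue carrying ``ligand`` plus a terminal trimethylammonium.

    ``protonated=True`` protonates every triazole N3 (ligand becomes
    triazolium, +1 e per side-chain on top of the ammonium +1 e).
    """
    ligand = LigandKind.coerce(ligand)
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if ligand is LigandKind.WATER:
        raise ValueError("water is not a side-chain ligand")
    if protonated:
        if ligand not in (LigandKind.TRIAZOLE, LigandKind.TRIAZOLIUM):
            raise ValueError(
                f"ligand {ligand.value!r} has no protonatable site"
            )
        ligand = LigandKind.TRIAZOLE  # store base kind; flag carries the state
    elif ligand is LigandKind.TRIAZOLIUM:
        # asking for triazolium IS asking for the protonated triazole
        ligand, protonated = LigandKind.TRIAZOLE, True

    protonation = tuple(bool(protonated) for _ in range(n_residues))
    atoms = _assemble_atoms(n_residues, ligand, protonation)
    return PeptideModel(
        n_residues=n_residues,
        base_ligand=ligand,
        protonation=protonation,
        atoms=atoms,
    )


def set_protonation(model: PeptideModel, flags: Sequence[bool]) -> PeptideModel:
    """Return a model with the given per-residue protonation pattern
    (mixed-state ensembles at intermediate pH are the caller's business)."""
    if model.base_ligand is not LigandKind.TRIAZOLE:
        raise ValueError("only triazole side-chains are protonatable")
    flags = tuple(bool(f) for f in flags)
    if len(flags) != model.n_residues:
        raise ValueError("need one protonation flag per residue")
    atoms = _assemble_atoms(model.n_residues, model.base_ligand, flags)
    return PeptideModel(
        n_residues=model.n_residues,
        base_ligand=model.base_ligand,
        protonation=flags,
        atoms=atoms,
    )


def _assemble_atoms(
    n_residues: int,
    ligand: LigandKind,
    protonation: Sequence[bool],
) -> list[AtomSite]:
    atoms: list[AtomSite] = []
    idx = 0
    for r in range(n_residues):
        if ligand is LigandKind.TRIAZOLE:
            kind = LigandKind.TRIAZOLIUM if protonation[r] else LigandKind.TRIAZOLE
        else:
            kind = ligand
        for name in BACKBONE_ATOM_NAMES:
            element = name[0] if name != "CA" else "C"
            charge = 0
            # zwitterionic termini: +1 on the N-terminal amine nitrogen,
            # -1 on the C-terminal carboxylate oxygen
            if r == 0 and name == "N":
                charge = 1
            if r == n_residues - 1 and name == "O":
                charge = -1
            atoms.append(AtomSite(idx, name, r, element, "backbone", charge))
            idx += 1
        for name, element, group, charge in _SIDECHAIN_LAYOUT[kind]:
            atoms.append(AtomSite(idx, name, r, element, group, charge))
            idx += 1
    return atoms


def charge_ledger(model: PeptideModel) -> ChargeLedger:
    """Per-residue side-chain formal charges; termini tracked separately."""
    per_res = [0] * model.n_residues
    termini = 0
    for a in model.atoms:
        if a.charge == 0:
            continue
        is_terminal = (a.residue == 0 and a.name == "N") or (
            a.residue == model.n_residues - 1 and a.name == "O"
        )
        if is_terminal:
            termini += a.charge
        else:
            per_res[a.residue] += a.charge
    return ChargeLedger(per_residue=tuple(per_res), termini=termini)


def net_formal_charge(model: PeptideModel) -> int:
    """Net formal charge (e): sum of side-chain charges; the zwitterionic
    termini (+1/-1) cancel."""
    return charge_ledger(model).net
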