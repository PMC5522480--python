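"""Synthetic inputs for every stage of the pipeline.

Emulates, with controlled statistical structure, the data the analyses
expect from molecular-dynamics trajectories and a small-angle neutron
scattering beamline:

* peptide conformations (ideal helices, self-avoiding random coils,
  thermally perturbed copies) with full backbone N/H/CA/C/O atoms and
  coarse side-chains matched to a :class:`~helixsans.peptide_model.PeptideModel`;
* solvated frames - geometric water (rigid O + 2 H) placed uniformly in a
  cubic periodic box, optionally with a planted depletion sphere around
  the backbone centre of mass;
* trajectories - stable helix / stable coil ensembles and coil-to-helix
  "folding" traces built by geometric interpolation (no physics);
* noisy multi-contrast SANS curves from the forward model of
  :mod:`helixsans.sans_model`;
* Henderson-Hasselbalch titration tables.

Everything is bit-reproducible given a seed. Backbone atoms are placed from
the C-alpha trace using fixed local-frame offsets calibrated against a
standard alpha-helical backbone (phi = -57 deg, psi = -47 deg), so an ideal
helix generated here carries the canonical i -> i+4 backbone H-bond ladder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .peptide_model import (
    LigandKind,
    PeptideModel,
    build_topology,
)
from .sans_model import (
    ContrastSeries,
    SANSCurve,
    SANSModelParams,
    composite_intensity,
    particle_sld,
    solvent_sld,
)

__all__ = [
    "Conformation",
    "Frame",
    "Trajectory",
    "TitrationCurve",
    "IDEAL_RADIUS_NM",
    "IDEAL_TWIST_DEG",
    "IDEAL_RISE_NM",
    "CA_CA_BOND_NM",
    "generate_ideal_helix",
    "generate_random_coil",
    "perturb_conformation",
    "solvate",
    "generate_trajectory",
    "simulate_sans_curve",
    "simulate_contrast_series",
    "simulate_titration",
    "default_q_grid",
    "contrast_preset",
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "write_sans_curve",
    "read_sans_curve",
]

# canonical ideal alpha-helix C-alpha geometry (nm / degrees):
# radius and twist as commonly quoted for the ideal helix; rise is the
# textbook 0.15 nm per residue; virtual C-alpha bond 0.38 nm.
IDEAL_RADIUS_NM = 0.23
IDEAL_TWIST_DEG = 100.0
IDEAL_RISE_NM = 0.15
CA_CA_BOND_NM = 0.38

# Backbone offsets (nm) in the local C-alpha frame [a, b, c]:
# a = unit(CA[i+1]-CA[i-1]) (chain tangent), b = unit component of
# CA[i-1]+CA[i+1]-2 CA[i] perpendicular to a (points toward the helix
# axis), c = a x b. Calibrated once from a NeRF-built ideal helix with
# standard internal coordinates; exact to <1e-6 nm on that template.
_BACKBONE_OFFSETS = {
    "N": (-0.10978, 0.08907, -0.03565),
    "H": (-0.14944, 0.08275, -0.12833),
    "C": (0.12253, 0.07880, 0.04510),
    "O": (0.18347, 0.04749, 0.14737),
}

# side-chain offsets (nm) along the outward normal u = -b and tangent a;
# pseudo-linker every 0.15 nm, ligand ring ~0.45 nm out, terminal
# ammonium 0.9 nm out. Entries: name -> (along_u, along_a).
_SIDECHAIN_OFFSETS = {
    "L1": (0.15, 0.0),
    "L2": (0.30, 0.0),
    "C5": (0.45, 0.11),
    "H5": (0.512, 0.188),
    "N3": (0.45, -0.11),
    "H3": (0.512, -0.188),
    "CS": (0.45, 0.11),
    "OS": (0.45, -0.11),
    "NS": (0.512, 0.188),
    "HS": (0.612, 0.188),
    "L3": (0.60, 0.0),
    "L4": (0.75, 0.0),
    "NT": (0.90, 0.0),
}

_WATER_OH_NM = 0.1
_WATER_HOH_DEG = 104.5


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------
@dataclass
class Conformation:
    """Coordinates (nm) matched 1:1 to a :class:`PeptideModel`."""

    coords: np.ndarray  # (n_atoms, 3) nm
    model: PeptideModel

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.model.n_atoms, 3):
            raise ValueError(
                f"coordinate array {self.coords.shape} does not match "
                f"model with {self.model.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def calpha(self) -> np.ndarray:
        idx = [self.model.atom(r, "CA").index for r in range(self.model.n_residues)]
        return self.coords[idx]

    def backbone(self) -> np.ndarray:
        return self.coords[self.model.backbone_indices()]


@dataclass
class Frame:
    """One solvated snapshot: peptide + rigid waters in a cubic box."""

    conformation: Conformation
    water_o: np.ndarray          # (n_w, 3) nm
    water_h: np.ndarray          # (n_w, 2, 3) nm
    box_edge: float              # nm
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.water_o = np.asarray(self.water_o, dtype=float).reshape(-1, 3)
        self.water_h = np.asarray(self.water_h, dtype=float).reshape(-1, 2, 3)
        if self.water_h.shape[0] != self.water_o.shape[0]:
            raise ValueError("each water O needs exactly two H")
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")

    @property
    def n_waters(self) -> int:
        return self.water_o.shape[0]


@dataclass
class Trajectory:
    """Time-ordered frames with a uniform step."""

    frames: list[Frame]
    time_step_ns: float

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        n0 = self.frames[0].conformation.model.n_atoms
        for f in self.frames:
            if f.conformation.model.n_atoms != n0:
                raise ValueError("atom count must be constant across frames")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def times_ns(self) -> np.ndarray:
        return np.array([f.time_ns for f in self.frames])


@dataclass
class TitrationCurve:
    """pH grid and protonated fraction at each pH."""

    ph: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.ph.size == 0:
            raise ValueError("empty pH grid")
        if self.ph.shape != self.fraction.shape:
            raise ValueError("pH and fraction grids differ in length")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")


# ----------------------------------------------------------------------
# conformation generators
# ----------------------------------------------------------------------
def _frames_from_extended_ca(ca_ext: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local frames for residues 0..n-1 given a trace with one virtual
    C-alpha prepended and appended (shape (n+2, 3))."""
    prev, cur, nxt = ca_ext[:-2], ca_ext[1:-1], ca_ext[2:]
    a = nxt - prev
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b = prev + nxt - 2.0 * cur
    b -= np.sum(b * a, axis=1, keepdims=True) * a
    norm = np.linalg.norm(b, axis=1, keepdims=True)
    # degenerate (locally collinear) trace: pick any perpendicular
    bad = norm[:, 0] < 1e-9
    if np.any(bad):
        for i in np.where(bad)[0]:
            t = np.array([1.0, 0.0, 0.0])
            if abs(a[i] @ t) > 0.9:
                t = np.array([0.0, 1.0, 0.0])
            p = t - (t @ a[i]) * a[i]
            b[i] = p
            norm[i] = np.linalg.norm(p)
    b /= norm
    c = np.cross(a, b)
    return a, b, c


def _full_coords_from_ca(model: PeptideModel, ca_ext: np.ndarray) -> np.ndarray:
    """Place all atoms from an extended C-alpha trace (n+2 points)."""
    n = model.n_residues
    if ca_ext.shape != (n + 2, 3):
        raise ValueError("extended trace must have n_residues + 2 points")
    a, b, c = _frames_from_extended_ca(ca_ext)
    ca = ca_ext[1:-1]
    coords = np.empty((model.n_atoms, 3))
    for atom in model.atoms:
        r = atom.residue
        if atom.name == "CA":
            coords[atom.index] = ca[r]
        elif atom.name in _BACKBONE_OFFSETS:
            xa, xb, xc = _BACKBONE_OFFSETS[atom.name]
            coords[atom.index] = ca[r] + xa * a[r] + xb * b[r] + xc * c[r]
        else:
            du, da = _SIDECHAIN_OFFSETS[atom.name]
            coords[atom.index] = ca[r] - du * b[r] + da * a[r]
    return coords


def _extend_linear(ca: np.ndarray) -> np.ndarray:
    """Pad a C-alpha trace with linearly extrapolated virtual ends."""
    first = 2.0 * ca[0] - ca[1]
    last = 2.0 * ca[-1] - ca[-2]
    return np.vstack([first, ca, last])


def _helix_ca(n: int, radius: float, twist_deg: float, rise: float,
              start: int = 0) -> np.ndarray:
    i = np.arange(start, start + n)
    th = np.radians(twist_deg) * i
    return np.c_[radius * np.cos(th), radius * np.sin(th), rise * i]


def generate_ideal_helix(
    n_residues: int,
    radius: float = IDEAL_RADIUS_NM,
    twist: float = IDEAL_TWIST_DEG,
    rise: float = IDEAL_RISE_NM,
    model: PeptideModel | None = None,
) -> Conformation:
    """Right-handed ideal helix: C-alpha atoms exactly on a cylindrical
    helix of the given radius (nm), per-residue twist (deg) and rise (nm);
    other backbone atoms at canonical alpha-helical internal geometry.

    ``model`` defaults to the fully protonated (triazolium) chain, the
    helical state of the study system.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if radius <= 0 or rise <= 0:
        raise ValueError("radius and rise must be positive")
    if not 0.0 < twist < 180.0:
        raise ValueError("twist must lie in (0, 180) degrees")
    if model is None:
        model = build_topology(n_residues, LigandKind.TRIAZOLE, protonated=True)
    if model.n_residues != n_residues:
        raise ValueError("model size does not match n_residues")
    # virtual residues at i = -1 and i = n keep every frame exactly helical
    ca_ext = _helix_ca(n_residues + 2, radius, twist, rise, start=-1)
    return Conformation(_full_coords_from_ca(model, ca_ext), model)


def generate_random_coil(
    n_residues: int,
    seed: int,
    model: PeptideModel | None = None,
    step: float = CA_CA_BOND_NM,
    min_separation: float = 0.4,
    max_restarts: int = 200,
) -> Conformation:
    """Self-avoiding random-walk C-alpha trace (fixed 0.38 nm steps, no two
    non-bonded C-alpha closer than ``min_separation``), with backbone and
    side-chain atoms rebuilt from local frames. Deterministic per seed."""
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if model is None:
        model = build_topology(n_residues, LigandKind.TRIAZOLE, protonated=False)
    if model.n_residues != n_residues:
        raise ValueError("model size does not match n_residues")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        ca = _try_saw(rng, n_residues, step, min_separation)
        if ca is not None:
            return Conformation(
                _full_coords_from_ca(model, _extend_linear(ca)), model
            )
    raise RuntimeError(
        f"self-avoiding walk failed to place {n_residues} residues "
        f"after {max_restarts} restarts"
    )


def _try_saw(rng: np.random.Generator, n: int, step: float,
             min_sep: float) -> np.ndarray | None:
    pts = np.zeros((n, 3))
    pts[1] = (0.0, 0.0, step)
    for i in range(2, n):
        for _ in range(60):
            v = rng.normal(size=3)
            v *= step / np.linalg.norm(v)
            cand = pts[i - 1] + v
            d = np.linalg.norm(pts[: i - 1] - cand, axis=1)
            if np.all(d >= min_sep):
                pts[i] = cand
                break
        else:
            return None
    return pts


def perturb_conformation(
    conf: Conformation, amplitude: float, seed: int
) -> Conformation:
    """Isotropic Gaussian displacement of every atom, per-axis standard
    deviation ``amplitude`` (nm). Zero amplitude returns the input exactly."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude == 0.0:
        return Conformation(conf.coords.copy(), conf.model)
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=amplitude, size=conf.coords.shape)
    return Conformation(conf.coords + noise, conf.model)


# ----------------------------------------------------------------------
# solvation
# ----------------------------------------------------------------------
def solvate(
    conf: Conformation,
    box_edge: float,
    n_waters: int,
    depletion_radius: float = 0.0,
    seed: int = 0,
    clash_distance: float = 0.25,
    hbond_oriented: bool = True,
    time_ns: float = 0.0,
) -> Frame:
    """Drop rigid waters uniformly into a cubic box around the peptide,
    excluding a sphere of ``depletion_radius`` about the backbone centre of
    mass and ``clash_distance`` clashes with peptide atoms (minimum image).

    With ``hbond_oriented`` (the default) a water sitting within H-bond
    range (0.35 nm) of a peptide acceptor points one O-H at the nearest
    such acceptor, emulating the orientational ordering real water shows in
    the first hydration shell; all other waters are oriented uniformly at
    random. Set ``clash_distance=0`` for pure planted-depletion recovery
    studies where only the COM exclusion sphere should shape g(r).

    The peptide is translated so its backbone centre of mass sits at the
    box centre.
    """
    if n_waters < 0:
        raise ValueError("n_waters must be >= 0")
    if depletion_radius < 0:
        raise ValueError("depletion_radius must be >= 0")
    model = conf.model
    bb = conf.backbone()
    masses = np.array([model.atoms[i].mass for i in model.backbone_indices()])
    com = masses @ bb / masses.sum()
    extent = np.ptp(conf.coords, axis=0).max()
    if box_edge <= extent:
        raise ValueError(
            f"box edge {box_edge} nm smaller than peptide extent {extent:.2f} nm"
        )
    centre = np.full(3, box_edge / 2.0)
    coords = conf.coords + (centre - com)
    peptide = Conformation(coords, model)

    rng = np.random.default_rng(seed)
    placed = np.empty((n_waters, 3))
    count = 0
    attempts = 0
    max_attempts = max(200_000, 400 * max(n_waters, 1))
    while count < n_waters:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placed only {count}/{n_waters} waters; box too small for "
                "the requested exclusions"
            )
        m = min(4096, max_attempts - attempts)
        attempts += m
        cand = rng.uniform(0.0, box_edge, size=(m, 3))
        ok = _min_image_dist(cand, centre[None, :], box_edge).min(axis=1) >= depletion_radius
        if np.any(ok):
            cand = cand[ok]
            d = _min_image_dist(cand, coords, box_edge)
            cand = cand[d.min(axis=1) >= clash_distance]
            take = min(len(cand), n_waters - count)
            placed[count : count + take] = cand[:take]
            count += take
    if hbond_oriented and n_waters > 0:
        acc_idx = [i for i, _ in model.acceptor_sites()]
        water_h = _water_hydrogens(
            rng, placed, coords[acc_idx], box_edge
        )
    else:
        water_h = _water_hydrogens(rng, placed)
    return Frame(peptide, placed, water_h, box_edge, time_ns=time_ns)


def _min_image_dist(a: np.ndarray, b: np.ndarray, box: float) -> np.ndarray:
    """Pairwise minimum-image distances between point sets (cubic box)."""
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=-1)


def _water_hydrogens(
    rng: np.random.Generator,
    o: np.ndarray,
    acceptors: np.ndarray | None = None,
    box: float | None = None,
    hbond_range: float = 0.35,
) -> np.ndarray:
    """Two H per O: rigid 0.1 nm bonds, 104.5 deg angle.

    Randomly oriented, except that a water within ``hbond_range`` of one of
    the ``acceptors`` points its first O-H at the nearest one (first-shell
    orientational ordering).
    """
    n = o.shape[0]
    half = math.radians(_WATER_HOH_DEG / 2.0)
    local = _WATER_OH_NM * np.array(
        [
            [0.0, 0.0, 1.0],
            [math.sin(_WATER_HOH_DEG / 180.0 * math.pi), 0.0,
             math.cos(_WATER_HOH_DEG / 180.0 * math.pi)],
        ]
    )
    del half
    target: np.ndarray | None = None
    if acceptors is not None and len(acceptors) and n:
        from scipy.spatial import cKDTree

        tree = cKDTree(np.mod(acceptors, box), boxsize=box)
        dist, idx = tree.query(np.mod(o, box), k=1)
        target = np.where(dist[:, None] <= hbond_range,
                          acceptors[idx], np.nan)
    hs = np.empty((n, 2, 3))
    for i in range(n):
        rot = _random_rotation(rng)
        if target is not None and np.isfinite(target[i, 0]):
            # z-axis of the local frame -> unit vector toward the acceptor
            d = target[i] - o[i]
            d -= box * np.round(d / box)
            z = d / np.linalg.norm(d)
            x = _perpendicular(z, rng)
            rot = np.c_[x, np.cross(z, x), z]
        hs[i] = o[i] + local @ rot.T
    return hs


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    t = rng.normal(size=3)
    p = t - (t @ v) * v
    return p / np.linalg.norm(p)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ----------------------------------------------------------------------
# trajectories
# ----------------------------------------------------------------------
TRAJECTORY_KINDS = ("stable_coil", "stable_helix", "folding")

#: default thermal-noise amplitude (nm): chosen so the helical-state
#: C-alpha RMSD to the ideal helix sits near 0.04 nm, the magnitude the
#: study system shows in its folded state.
DEFAULT_AMPLITUDE_NM = 0.025
#: fraction of frames over which the folding kind completes its
#: coil-to-helix interpolation.
DEFAULT_SWITCH_FRACTION = 0.4


def generate_trajectory(
    model: PeptideModel,
    kind: str,
    n_frames: int,
    time_step: float,
    seed: int,
    amplitude: float = DEFAULT_AMPLITUDE_NM,
    switch_fraction: float = DEFAULT_SWITCH_FRACTION,
    n_waters: int = 0,
    box_edge: float = 6.0,
    depletion_radius: float = 0.0,
) -> Trajectory:
    """Synthetic trajectory of the requested kind.

    ``stable_helix`` / ``stable_coil`` perturb one reference conformation
    per frame; ``folding`` interpolates linearly from a coil to the ideal
    helix, completing at ``switch_fraction`` of the run, then stays folded.
    Waters (if any) are re-drawn each frame.
    """
    if kind not in TRAJECTORY_KINDS:
        raise ValueError(f"unknown trajectory kind {kind!r}; use one of {TRAJECTORY_KINDS}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    helix = generate_ideal_helix(model.n_residues, model=model)
    coil = generate_random_coil(
        model.n_residues, seed=int(rng.integers(2**31)), model=model
    )
    # align the coil to the helix so folding interpolation stays local
    coil = Conformation(
        _superpose(coil.coords, helix.coords), model
    )

    frames: list[Frame] = []
    for t in range(n_frames):
        if kind == "stable_helix":
            base = helix.coords
        elif kind == "stable_coil":
            base = coil.coords
        else:
            switch = switch_fraction * max(n_frames - 1, 1)
            lam = 1.0 if switch <= 0 else min(t / switch, 1.0)
            base = (1.0 - lam) * coil.coords + lam * helix.coords
        conf = perturb_conformation(
            Conformation(base, model), amplitude, seed=int(rng.integers(2**31))
        )
        if n_waters > 0:
            frame = solvate(
                conf,
                box_edge,
                n_waters,
                depletion_radius=depletion_radius,
                seed=int(rng.integers(2**31)),
                time_ns=t * time_step,
            )
        else:
            frame = Frame(conf, np.empty((0, 3)), np.empty((0, 2, 3)),
                          box_edge, time_ns=t * time_step)
        frames.append(frame)
    return Trajectory(frames, time_step_ns=time_step)


def _superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition (Kabsch) of mobile onto target."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + target.mean(axis=0)


# ----------------------------------------------------------------------
# SANS + titration
# ----------------------------------------------------------------------
#: instrument q range (A^-1) the synthetic curves emulate
Q_MIN, Q_MAX = 0.0057, 0.32


def default_q_grid(n_points: int = 80) -> np.ndarray:
    """Logarithmic q grid over the emulated instrument range."""
    return np.geomspace(Q_MIN, Q_MAX, n_points)


def simulate_sans_curve(
    params: SANSModelParams,
    q_grid: np.ndarray | None = None,
    relative_noise: float = 0.02,
    seed: int = 0,
) -> SANSCurve:
    """Forward-model intensity plus zero-mean Gaussian noise with
    sigma_I = relative_noise * I; the sigma column records that value."""
    if q_grid is None:
        q_grid = default_q_grid()
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or q.size == 0 or np.any(q <= 0) or np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly positive and increasing")
    if relative_noise < 0:
        raise ValueError("relative_noise must be >= 0")
    intensity = composite_intensity(q, params)
    sigma = relative_noise * intensity
    rng = np.random.default_rng(seed)
    noisy = intensity + rng.normal(scale=1.0, size=q.size) * sigma
    return SANSCurve(q=q, intensity=noisy, sigma=sigma,
                     d2o_fraction=params.d2o_fraction)


# presets emulating the two measured solution conditions: same cylinder
# radius, a slightly longer and drier cylinder in the helical (acidic)
# state than in the coil (basic) state.
_PRESETS = {
    "pH2": dict(radius_a=13.0, length_a=75.0, phi_water=0.51),
    "pH8": dict(radius_a=13.0, length_a=62.0, phi_water=0.59),
}
#: dry-particle SLD (1e-6 A^-2): generic protonated organic polymer value.
DEFAULT_SLD_DRY = 2.0
#: plausible interaction defaults for the charged-cylinder structure factor
DEFAULT_VOLFRACTION = 0.005
DEFAULT_CHARGE = 20.0
DEFAULT_SCREENING_A = 30.0
DEFAULT_D2O_FRACTIONS = (1.0, 0.75, 0.50)
#: low-q surface-scattering term: amplitude set so the power law dominates
#: the signal below ~0.017 A^-1 (as the measured curves show) while the
#: cylinder term carries the rest; exponent inside the observed 3.5-3.7 band.
DEFAULT_POWERLAW_EXPONENT = 3.6
DEFAULT_POWERLAW_AMPLITUDE = 2.0e-6
DEFAULT_BACKGROUND = 0.001


def contrast_preset(name: str) -> dict:
    """Geometry/water-fraction preset for the two study conditions
    ('pH2': helical, 'pH8': coil)."""
    key = name.replace(".0", "").replace("pH ", "pH").replace("ph", "pH")
    if key not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; use 'pH2' or 'pH8'")
    return dict(_PRESETS[key])


def simulate_contrast_series(
    geometry: dict | str,
    phi_water: float | None = None,
    sld_dry: float = DEFAULT_SLD_DRY,
    d2o_fractions: Sequence[float] = DEFAULT_D2O_FRACTIONS,
    relative_noise: float = 0.02,
    seed: int = 0,
    q_grid: np.ndarray | None = None,
) -> ContrastSeries:
    """One noisy curve per solvent contrast, all sharing particle geometry.

    ``geometry`` is either a preset name ('pH2'/'pH8') or a dict with keys
    ``radius_a``, ``length_a`` (and optionally ``phi_water``). The particle
    SLD at each contrast is the water-volume-fraction mix
    phi_water * SLD_solvent + (1 - phi_water) * sld_dry.
    """
    if isinstance(geometry, str):
        geometry = contrast_preset(geometry)
    geometry = dict(geometry)
    if phi_water is None:
        phi_water = geometry.get("phi_water")
    if phi_water is None:
        raise ValueError("phi_water must be given explicitly or by the preset")
    if not 0.0 <= phi_water <= 1.0:
        raise ValueError("phi_water must lie in [0, 1]")
    fractions = list(d2o_fractions)
    if not fractions:
        raise ValueError("need at least one contrast")
    if len(set(fractions)) != len(fractions):
        raise ValueError("D2O fractions must be distinct")
    rng = np.random.default_rng(seed)
    curves = []
    for frac in fractions:
        sld_s = solvent_sld(frac)
        sld_p = particle_sld(phi_water, sld_dry, sld_s)
        params = SANSModelParams(
            radius_a=geometry["radius_a"],
            length_a=geometry["length_a"],
            sld_particle=sld_p,
            sld_solvent=sld_s,
            volfraction=geometry.get("volfraction", DEFAULT_VOLFRACTION),
            charge=geometry.get("charge", DEFAULT_CHARGE),
            screening_length_a=geometry.get("screening_length_a", DEFAULT_SCREENING_A),
            powerlaw_amplitude=geometry.get(
                "powerlaw_amplitude", DEFAULT_POWERLAW_AMPLITUDE
            ),
            powerlaw_exponent=geometry.get(
                "powerlaw_exponent", DEFAULT_POWERLAW_EXPONENT
            ),
            background=geometry.get("background", DEFAULT_BACKGROUND),
            d2o_fraction=frac,
        )
        curves.append(
            simulate_sans_curve(
                params, q_grid, relative_noise, seed=int(rng.integers(2**31))
            )
        )
    return ContrastSeries(curves=curves)


def simulate_titration(
    pka: float,
    ph_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """Henderson-Hasselbalch protonated fraction 1/(1+10^(pH-pKa)) plus
    Gaussian noise, clipped to [0, 1]."""
    ph = np.asarray(ph_grid, dtype=float)
    if ph.size == 0:
        raise ValueError("empty pH grid")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    frac = 1.0 / (1.0 + 10.0 ** (ph - pka))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frac = frac + rng.normal(scale=noise_sd, size=ph.shape)
    return TitrationCurve(ph=ph, fraction=np.clip(frac, 0.0, 1.0))


# ----------------------------------------------------------------------
# I/O: multi-model PDB and 3-column ASCII curves
# ----------------------------------------------------------------------
def write_trajectory_pdb(traj: Trajectory, path: str) -> None:
    """Multi-model PDB: one MODEL per frame, CRYST1 for the box, chain A
    for the peptide, HOH residues for water. Coordinates written in A."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    model = traj.frames[0].conformation.model
    n_w = traj.frames[0].n_waters
    n_atoms = model.n_atoms + 3 * n_w
    arrays = []
    for frame in traj.frames:
        if frame.n_waters != n_w:
            raise ValueError("PDB export needs a constant water count")
        arr = struc.AtomArray(n_atoms)
        arr.coord = np.empty((n_atoms, 3), dtype=np.float32)
        arr.coord[: model.n_atoms] = frame.conformation.coords * 10.0
        names, resids, resnames, chains, elements = [], [], [], [], []
        for a in model.atoms:
            names.append(a.name)
            resids.append(a.residue + 1)
            resnames.append("PEP")
            chains.append("A")
            elements.append(a.element)
        k = model.n_atoms
        for w in range(n_w):
            arr.coord[k] = frame.water_o[w] * 10.0
            arr.coord[k + 1] = frame.water_h[w, 0] * 10.0
            arr.coord[k + 2] = frame.water_h[w, 1] * 10.0
            for nm, el in (("O", "O"), ("H1", "H"), ("H2", "H")):
                names.append(nm)
                resids.append(model.n_residues + 1 + w)
                resnames.append("HOH")
                chains.append("W")
                elements.append(el)
            k += 3
        arr.atom_name = np.array(names)
        arr.res_id = np.array(resids)
        arr.res_name = np.array(resnames)
        arr.chain_id = np.array(chains)
        arr.element = np.array(elements)
        arr.box = np.eye(3) * frame.box_edge * 10.0
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def read_trajectory_pdb(
    path: str, model: PeptideModel, time_step_ns: float = 1.0
) -> Trajectory:
    """Read a multi-model PDB written by :func:`write_trajectory_pdb`."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    box = pdb.get_structure(model=1).box
    edge = float(box[0, 0]) / 10.0 if box is not None else 0.0
    pep_mask = stack.res_name != "HOH"
    wat_mask = ~pep_mask
    frames = []
    for m in range(stack.stack_depth()):
        arr = stack[m]
        pep = arr.coord[pep_mask] / 10.0
        if pep.shape[0] != model.n_atoms:
            raise ValueError("PDB peptide atom count does not match the model")
        conf = Conformation(pep, model)
        wat = arr.coord[wat_mask] / 10.0
        n_w = wat.shape[0] // 3
        o = wat.reshape(n_w, 3, 3)[:, 0, :] if n_w else np.empty((0, 3))
        h = wat.reshape(n_w, 3, 3)[:, 1:, :] if n_w else np.empty((0, 2, 3))
        frames.append(Frame(conf, o, h, edge if edge > 0 else 1e9,
                            time_ns=m * time_step_ns))
    return Trajectory(frames, time_step_ns=time_step_ns)


def write_sans_curve(curve: SANSCurve, path: str) -> None:
    """Whitespace-delimited 3-column ASCII (q, I, sigma) with '#' headers."""
    header = (
        f"# d2o_fraction={curve.d2o_fraction}\n"
        "# q[1/A]  I[1/cm]  sigma_I[1/cm]"
    )
    np.savetxt(path, np.c_[curve.q, curve.intensity, curve.sigma],
               header=header, comments="")


def read_sans_curve(path: str) -> SANSCurve:
    """Read the 3-column dialect; the D2O fraction comes from a
    '# d2o_fraction=<x>' header line (NaN when absent)."""
    frac = float("nan")
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "d2o_fraction=" in line:
                frac = float(line.split("d2o_fraction=")[1].split()[0])
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    return SANSCurve(q=data[:, 0], intensity=data[:, 1], sigma=data[:, 2],
                     d2o_fraction=frac)
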