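"""Helical-parameter fitting and RMSD to an ideal alpha-helix.

Given an ordered C-alpha trace the fitter recovers the helix axis, the
radius (mean perpendicular distance to the axis), the per-residue twist
(mean signed rotation of consecutive radial vectors about the axis) and the
per-residue rise, plus the C-alpha RMSD to an ideal reference helix after
optimal rigid superposition.

Axis estimation: second differences of consecutive C-alpha positions are
exactly perpendicular to the axis of a circular helix, so the axis is the
least-significant right singular vector of the stacked second differences;
(axis, centre) are then refined by nonlinear least squares minimising the
spread of perpendicular distances. Exact on noiseless input, robust under
thermal noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .synthetic_data import (
    IDEAL_RADIUS_NM,
    IDEAL_RISE_NM,
    IDEAL_TWIST_DEG,
    Trajectory,
    _helix_ca,
)

__all__ = [
    "HelixFit",
    "fit_helix",
    "rmsd_to_ideal_helix",
    "rmsd_time_trace",
    "DEFAULT_N_EXCLUDE",
]

#: default chain-end exclusion (two residues per end) used for noisy data;
#: exact synthetic helices are fitted with 0.
DEFAULT_N_EXCLUDE = 2


@dataclass
class HelixFit:
    """Fitted helix parameters for one conformation."""

    axis_point: np.ndarray       # point on the axis (nm)
    axis_direction: np.ndarray   # unit vector, oriented along the chain
    radius_nm: float
    twist_deg: float             # magnitude in (0, 180]
    rise_nm: float
    rmsd_helix_nm: float         # RMSD to the ideal reference helix
    handedness: int              # +1 right-handed, -1 left-handed
    n_excluded_termini: int
    degenerate: bool = False     # collinear trace; radius forced to 0

    def to_dict(self) -> dict:
        return {
            "axis_point_nm": [float(x) for x in self.axis_point],
            "axis_direction": [float(x) for x in self.axis_direction],
            "radius_nm": float(self.radius_nm),
            "twist_deg": float(self.twist_deg),
            "rise_nm": float(self.rise_nm),
            "rmsd_helix_nm": float(self.rmsd_helix_nm),
            "handedness": int(self.handedness),
            "n_excluded_termini": int(self.n_excluded_termini),
            "degenerate": bool(self.degenerate),
        }


def fit_helix(
    calpha: np.ndarray,
    n_exclude: int = 0,
    ideal_radius: float = IDEAL_RADIUS_NM,
    ideal_twist: float = IDEAL_TWIST_DEG,
    ideal_rise: float = IDEAL_RISE_NM,
) -> HelixFit:
    """Fit axis, radius, twist and rise to an ordered C-alpha trace (nm),
    excluding ``n_exclude`` residues at each end.

    A collinear trace cannot define a radius; it is returned flagged with
    radius 0 rather than raising.
    """
    ca = np.asarray(calpha, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("calpha must be an (n, 3) array")
    if n_exclude < 0:
        raise ValueError("n_exclude must be >= 0")
    inc = ca[n_exclude : len(ca) - n_exclude] if n_exclude else ca
    if len(inc) < 4:
        raise ValueError(
            f"need at least 4 C-alpha after exclusion, got {len(inc)}"
        )

    second = inc[:-2] - 2.0 * inc[1:-1] + inc[2:]
    steps = np.diff(inc, axis=0)
    if np.max(np.linalg.norm(second, axis=1)) < 1e-9 * np.max(
        np.linalg.norm(steps, axis=1)
    ):
        # straight line: direction from the steps, zero radius
        axis = steps.sum(axis=0)
        axis /= np.linalg.norm(axis)
        rise = float(np.mean(np.abs(steps @ axis)))
        rmsd = rmsd_to_ideal_helix(
            ca, ideal_radius, ideal_twist, ideal_rise, n_exclude=n_exclude
        )
        return HelixFit(
            axis_point=inc.mean(axis=0),
            axis_direction=axis,
            radius_nm=0.0,
            twist_deg=0.0,
            rise_nm=rise,
            rmsd_helix_nm=rmsd,
            handedness=1,
            n_excluded_termini=n_exclude,
            degenerate=True,
        )

    # initial axis: second differences span the plane perpendicular to it
    _, _, vt = np.linalg.svd(second)
    axis = vt[-1]
    if (steps.sum(axis=0) @ axis) < 0:
        axis = -axis
    centre = _circle_centre(inc, axis)
    axis, centre = _refine_axis(inc, axis, centre)
    if (steps.sum(axis=0) @ axis) < 0:
        axis = -axis

    rel = inc - centre
    z = rel @ axis
    radial = rel - np.outer(z, axis)
    dists = np.linalg.norm(radial, axis=1)
    radius = float(dists.mean())

    # signed rotation between consecutive radial vectors about the axis
    r0, r1 = radial[:-1], radial[1:]
    cross = np.cross(r0, r1)
    sin_t = cross @ axis
    cos_t = np.sum(r0 * r1, axis=1)
    angles = np.degrees(np.arctan2(sin_t, cos_t))
    mean_angle = float(np.mean(angles))
    handedness = 1 if mean_angle >= 0 else -1
    twist = abs(mean_angle)
    if twist > 180.0:
        twist = 360.0 - twist
    rise = float(np.mean(np.abs(np.diff(z))))
    rmsd = rmsd_to_ideal_helix(
        ca, ideal_radius, ideal_twist, ideal_rise, n_exclude=n_exclude
    )
    return HelixFit(
        axis_point=centre,
        axis_direction=axis,
        radius_nm=radius,
        twist_deg=twist,
        rise_nm=rise,
        rmsd_helix_nm=rmsd,
        handedness=handedness,
        n_excluded_termini=n_exclude,
    )


def _circle_centre(pts: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Kasa algebraic circle fit of the points projected along ``axis``
    (exact when the projections lie on a circle)."""
    e1 = _any_perpendicular(axis)
    e2 = np.cross(axis, e1)
    xy = np.c_[pts @ e1, pts @ e2]
    a = np.c_[2.0 * xy, np.ones(len(xy))]
    b = (xy**2).sum(axis=1)
    (cx, cy, _), *_ = np.linalg.lstsq(a, b, rcond=None)
    z_mean = (pts @ axis).mean()
    return cx * e1 + cy * e2 + z_mean * axis


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    t = np.array([1.0, 0.0, 0.0])
    if abs(v @ t) > 0.9:
        t = np.array([0.0, 1.0, 0.0])
    p = t - (t @ v) * v
    return p / np.linalg.norm(p)


def _refine_axis(
    pts: np.ndarray, axis0: np.ndarray, centre0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nonlinear refinement: minimise the spread of perpendicular distances
    over axis orientation and in-plane centre offset."""
    e1 = _any_perpendicular(axis0)
    e2 = np.cross(axis0, e1)

    def unpack(x):
        th1, th2, c1, c2 = x
        axis = axis0 + th1 * e1 + th2 * e2
        axis = axis / np.linalg.norm(axis)
        centre = centre0 + c1 * e1 + c2 * e2
        return axis, centre

    def resid(x):
        axis, centre = unpack(x)
        rel = pts - centre
        radial = rel - np.outer(rel @ axis, axis)
        d = np.linalg.norm(radial, axis=1)
        return d - d.mean()

    sol = least_squares(resid, np.zeros(4), method="lm", xtol=1e-15, ftol=1e-15)
    return unpack(sol.x)


def rmsd_to_ideal_helix(
    calpha: np.ndarray,
    ideal_radius: float = IDEAL_RADIUS_NM,
    ideal_twist: float = IDEAL_TWIST_DEG,
    ideal_rise: float = IDEAL_RISE_NM,
    n_exclude: int = 0,
) -> float:
    """C-alpha RMSD (nm) to an ideal helix of matching residue count after
    optimal least-squares rigid superposition over the included atoms."""
    ca = np.asarray(calpha, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError("calpha must be an (n, 3) array")
    inc = ca[n_exclude : len(ca) - n_exclude] if n_exclude else ca
    if len(inc) < 3:
        raise ValueError("need at least 3 C-alpha after exclusion")
    ideal = _helix_ca(len(inc), ideal_radius, ideal_twist, ideal_rise)
    return _superposed_rmsd(inc, ideal)


def _superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Kabsch: optimal proper-rotation superposition RMSD of a onto b."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = ac @ rot - bc
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def rmsd_time_trace(
    traj: Trajectory,
    ideal_radius: float = IDEAL_RADIUS_NM,
    ideal_twist: float = IDEAL_TWIST_DEG,
    ideal_rise: float = IDEAL_RISE_NM,
    n_exclude: int = 0,
) -> np.ndarray:
    """RMSD_helix per frame: array of (time ns, rmsd nm) rows in frame
    order. A frame that cannot be evaluated yields NaN with a warning
    instead of aborting the trace."""
    out = np.empty((len(traj), 2))
    for i, frame in enumerate(traj):
        out[i, 0] = frame.time_ns
        try:
            out[i, 1] = rmsd_to_ideal_helix(
                frame.conformation.calpha(),
                ideal_radius,
                ideal_twist,
                ideal_rise,
                n_exclude=n_exclude,
            )
        except ValueError as exc:  # pragma: no cover - degenerate frames
            warnings.warn(f"frame {i}: {exc}", stacklevel=2)
            out[i, 1] = np.nan
    return out
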