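"""Radial distribution of water around the backbone centre of mass.

g(r) between the per-frame mass-weighted backbone centre of mass and the
water oxygen atoms, computed with minimum-image distances in the cubic box
and normalised by shell volume times the mean instantaneous water number
density, so a uniform ideal gas gives g = 1. Statistical errors come from
block averaging over contiguous trajectory blocks; the depletion radius is
the edge of the innermost region where g stays below a near-zero threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .peptide_model import PeptideModel
from .synthetic_data import Frame, Trajectory

__all__ = [
    "RDF",
    "backbone_com",
    "rdf_com_water",
    "block_average_rdf",
    "depletion_radius",
    "DEFAULT_BIN_WIDTH_NM",
    "DEFAULT_N_BLOCKS",
    "DEFAULT_DEPLETION_THRESHOLD",
]

DEFAULT_BIN_WIDTH_NM = 0.04
DEFAULT_N_BLOCKS = 5
DEFAULT_DEPLETION_THRESHOLD = 0.1


@dataclass
class RDF:
    """Binned g(r): uniform bins, per-bin standard errors."""

    bin_centers: np.ndarray   # nm
    g: np.ndarray
    stderr: np.ndarray
    bin_width: float          # nm
    n_frames: int
    errors_defined: bool = True   # False for single-block estimates

    def __post_init__(self) -> None:
        if np.any(self.g < 0) or np.any(self.stderr < 0):
            raise ValueError("g and errors must be non-negative")

    @property
    def r_max(self) -> float:
        return float(self.bin_centers[-1] + 0.5 * self.bin_width)


def backbone_com(frame_or_conf, model: PeptideModel) -> np.ndarray:
    """Mass-weighted mean of the backbone N/H/CA/C/O coordinates (nm)."""
    conf = getattr(frame_or_conf, "conformation", frame_or_conf)
    idx = model.backbone_indices()
    if not idx:
        raise ValueError("model has no backbone atoms")
    masses = np.array([model.atoms[i].mass for i in idx])
    return masses @ conf.coords[idx] / masses.sum()


def rdf_com_water(
    traj: Trajectory,
    model: PeptideModel,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
    r_max: float | None = None,
) -> RDF:
    """g(r) between backbone COM and water O over all frames (no error
    bars; see :func:`block_average_rdf` for block-averaged errors)."""
    g, n = _rdf_frames(list(traj), model, bin_width, r_max)
    centers = (np.arange(len(g)) + 0.5) * bin_width
    return RDF(centers, g, np.zeros_like(g), bin_width, n, errors_defined=False)


def _rdf_frames(
    frames: list[Frame],
    model: PeptideModel,
    bin_width: float,
    r_max: float | None,
) -> tuple[np.ndarray, int]:
    if not frames:
        raise ValueError("no frames")
    box = frames[0].box_edge
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0 + 1e-12:
        raise ValueError("r_max exceeds half the box edge")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if all(f.n_waters == 0 for f in frames):
        raise ValueError("no waters in any frame; RDF undefined")
    n_bins = int(np.floor(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    densities = []
    for f in frames:
        com = backbone_com(f, model)
        if f.n_waters:
            d = f.water_o - com
            d -= f.box_edge * np.round(d / f.box_edge)
            r = np.linalg.norm(d, axis=1)
            counts += np.histogram(r, bins=edges)[0]
        densities.append(f.n_waters / f.box_edge**3)
    rho = float(np.mean(densities))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (len(frames) * shell * rho)
    return g, len(frames)


def block_average_rdf(
    traj: Trajectory,
    model: PeptideModel,
    n_blocks: int = DEFAULT_N_BLOCKS,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
    r_max: float | None = None,
) -> RDF:
    """g(r) as the mean over ``n_blocks`` contiguous trajectory blocks with
    per-bin standard error = s.d. across blocks / sqrt(n_blocks). The last
    block absorbs any remainder frames. With a single block the errors are
    undefined and reported as zero (flagged)."""
    frames = list(traj)
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if len(frames) < n_blocks:
        raise ValueError(f"{len(frames)} frames cannot fill {n_blocks} blocks")
    size = len(frames) // n_blocks
    blocks = [frames[i * size : (i + 1) * size] for i in range(n_blocks - 1)]
    blocks.append(frames[(n_blocks - 1) * size :])
    gs = []
    for blk in blocks:
        g, _ = _rdf_frames(blk, model, bin_width, r_max)
        gs.append(g)
    gs = np.array(gs)
    mean = gs.mean(axis=0)
    if n_blocks == 1:
        warnings.warn(
            "single-block RDF: standard errors undefined, reported as zero",
            stacklevel=2,
        )
        err = np.zeros_like(mean)
    else:
        err = gs.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    centers = (np.arange(len(mean)) + 0.5) * bin_width
    return RDF(centers, mean, err, bin_width, len(frames),
               errors_defined=n_blocks > 1)


def depletion_radius(
    rdf: RDF, threshold: float = DEFAULT_DEPLETION_THRESHOLD
) -> float:
    """Largest r (nm) below which every bin has g < threshold: the radius
    of the water-free zone around the backbone COM. 0 when the first bin
    already reaches the threshold; r_max when no bin does."""
    above = np.where(rdf.g >= threshold)[0]
    if above.size == 0:
        return rdf.r_max
    k = int(above[0])
    return float(k * rdf.bin_width)


def write_rdf(rdf: RDF, path: str) -> None:
    """3-column ASCII: r (nm), g, standard error."""
    np.savetxt(
        path,
        np.c_[rdf.bin_centers, rdf.g, rdf.stderr],
        header="r[nm]  g  stderr",
    )
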