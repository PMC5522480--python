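"""Fitting of reduced SANS curves.

Three layers:

* low-q power-law characterisation (weighted log-log regression of the
  surface-scattering decay);
* bounded nonlinear least squares of the composite cylinder x structure-
  factor model to one curve or, with shared geometry, simultaneously to a
  multi-contrast series (trust-region reflective, finite-difference
  Jacobian, five jittered starts against local minima);
* the contrast-variation estimator: ordinary least squares of fitted
  particle SLD against solvent SLD, whose slope is the water volume
  fraction inside the particle and whose intercept is (1 - phi) times the
  dry-particle SLD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .sans_model import (
    ContrastSeries,
    SANSCurve,
    SANSModelParams,
    composite_intensity,
    solvent_sld,
    structure_factor,
)

__all__ = [
    "FitResult",
    "WaterFractionResult",
    "fit_powerlaw_exponent",
    "fit_single_curve",
    "fit_contrast_series",
    "water_fraction_from_slds",
    "DEFAULT_POWERLAW_WINDOW",
    "DEFAULT_SHARED",
    "DEFAULT_FIXED",
]

#: default q window (1/A) of the low-q surface-scattering decay
DEFAULT_POWERLAW_WINDOW = (0.006, 0.017)

#: parameters shared across contrasts in a simultaneous fit
DEFAULT_SHARED = ("radius_a", "length_a", "powerlaw_exponent")
#: parameters held fixed by default: the interaction nuisance parameters
#: (poorly determined by dilute data) and the intensity scale, which is
#: degenerate with the particle SLD under contrast variation
DEFAULT_FIXED = frozenset(
    {"volfraction", "charge", "screening_length_a", "scale"}
)

_FITTABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "radius_a": (1.0, 1e3),
    "length_a": (1.0, 1e4),
    "sld_particle": (-10.0, 15.0),
    "volfraction": (1e-8, 0.5),
    "charge": (0.0, 300.0),
    "screening_length_a": (0.5, 1e4),
    "powerlaw_amplitude": (0.0, 1.0),
    "powerlaw_exponent": (3.0, 4.0),
    "scale": (0.0, 1e6),
    "background": (0.0, 10.0),
}
_PER_CURVE = ("sld_particle", "scale", "powerlaw_amplitude", "background")


@dataclass
class FitResult:
    """Estimates, 1-sigma uncertainties and diagnostics of one fit."""

    params: dict[str, float]            # shared / single-curve estimates
    stderr: dict[str, float]
    per_curve: list[dict[str, float]]   # per-curve estimates (joint fits)
    per_curve_stderr: list[dict[str, float]]
    chi2: float
    reduced_chi2: float
    n_dof: int
    converged: bool
    singular: bool = False              # Jacobian rank-deficient at optimum
    message: str = ""

    @property
    def particle_slds(self) -> list[float]:
        return [pc["sld_particle"] for pc in self.per_curve]


@dataclass
class WaterFractionResult:
    """Water volume fraction from the SLD-vs-solvent regression."""

    phi_water: float
    sld_dry: float
    r_squared: float
    slope_stderr: float
    clipped: bool
    n_points: int


# ----------------------------------------------------------------------
def fit_powerlaw_exponent(
    curve: SANSCurve,
    q_window: tuple[float, float] = DEFAULT_POWERLAW_WINDOW,
) -> tuple[float, float]:
    """Power-law exponent n of I ~ q^-n over the window: weighted
    least-squares slope of log I vs log q, negated. Returns (n, stderr)."""
    lo, hi = q_window
    sel = (curve.q >= lo) & (curve.q <= hi)
    if sel.sum() < 4:
        raise ValueError(
            f"need at least 4 points in the window [{lo}, {hi}] A^-1"
        )
    q = curve.q[sel]
    intensity = curve.intensity[sel]
    sig = curve.sigma[sel]
    if np.any(intensity <= 0):
        raise ValueError("non-positive intensities in the power-law window")
    x = np.log(q)
    y = np.log(intensity)
    w = np.where(sig > 0, (intensity / np.where(sig > 0, sig, 1.0)) ** 2, 1.0)
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    resid = y - ym - slope * (x - xm)
    dof = max(len(x) - 2, 1)
    s2 = (w * resid**2).sum() / dof
    stderr = float(np.sqrt(s2 / sxx))
    n = -float(slope)
    if n < 1.0:
        warnings.warn(
            f"fitted exponent {n:.2f} is outside the surface-scattering "
            "band; the window may not contain a power-law decay",
            stacklevel=2,
        )
    return n, stderr


# ----------------------------------------------------------------------
def _valid_names(fixed) -> None:
    unknown = set(fixed) - set(_FITTABLE_BOUNDS)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")


def _weights(curve: SANSCurve) -> np.ndarray:
    if np.all(curve.sigma > 0):
        return 1.0 / curve.sigma
    warnings.warn(
        "non-positive sigma values: falling back to unit weights",
        stacklevel=3,
    )
    return np.ones_like(curve.sigma)


def _jitter_starts(
    x0: np.ndarray, lo: np.ndarray, hi: np.ndarray,
    n_starts: int, seed: int = 12345,
) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        x = x0 * (1.0 + rng.uniform(-0.2, 0.2, size=x0.shape))
        x += np.where(x0 == 0.0, rng.uniform(0, 0.1, size=x0.shape), 0.0)
        starts.append(np.clip(x, lo, hi))
    return starts


def _covariance(res) -> tuple[np.ndarray, bool]:
    """Parameter covariance from the Jacobian at the optimum."""
    jac = res.jac
    dof = max(jac.shape[0] - jac.shape[1], 1)
    s2 = 2.0 * res.cost / dof
    jtj = jac.T @ jac
    # rank check on the correlation-normalised matrix so that parameter
    # scale differences (SLD ~ 1 vs amplitude ~ 1e-6) do not masquerade as
    # rank deficiency
    d = np.sqrt(np.maximum(np.diag(jtj), 1e-300))
    corr = jtj / np.outer(d, d)
    sv = np.linalg.svd(corr, compute_uv=False)
    singular = bool(sv[-1] < 1e-10 * sv[0]) or bool(np.any(np.diag(jtj) == 0.0))
    cov = np.linalg.pinv(jtj) * s2
    return cov, singular


def fit_single_curve(
    curve: SANSCurve,
    init: SANSModelParams,
    fixed: frozenset[str] | set[str] = DEFAULT_FIXED,
    n_starts: int = 5,
) -> FitResult:
    """Bounded weighted least squares of the composite model to one curve.

    Parameters named in ``fixed`` are held at their ``init`` values; the
    remainder are free within physically sensible bounds.
    """
    _valid_names(fixed)
    free = [n for n in _FITTABLE_BOUNDS if n not in fixed]
    if not free:
        raise ValueError("no free parameters")
    w = _weights(curve)
    x0 = np.array([getattr(init, n) for n in free], dtype=float)
    lo = np.array([_FITTABLE_BOUNDS[n][0] for n in free])
    hi = np.array([_FITTABLE_BOUNDS[n][1] for n in free])
    x0 = np.clip(x0, lo, hi)

    def make_params(x: np.ndarray) -> SANSModelParams:
        return replace(init, **dict(zip(free, x)))

    # S(q) is held fixed while the geometry is refined and updated in a
    # short self-consistent outer loop: at the dilute fractions this model
    # targets, S barely moves with the equivalent-sphere diameter, and the
    # full rescaled-MSA solve per least-squares step would dominate runtime.
    s_of_q = structure_factor(curve.q, init)

    def resid(x: np.ndarray) -> np.ndarray:
        return (
            composite_intensity(curve.q, make_params(x), s_of_q=s_of_q)
            - curve.intensity
        ) * w

    best = None
    for start in _jitter_starts(x0, lo, hi, n_starts):
        try:
            res = least_squares(resid, start, bounds=(lo, hi), method="trf")
        except RuntimeError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is not None:
        # iterate S(q) to self-consistency with the fitted geometry
        for _ in range(4):
            prev = best.x.copy()
            s_of_q = structure_factor(curve.q, make_params(best.x))
            best = least_squares(resid, best.x, bounds=(lo, hi), method="trf")
            if np.max(np.abs(best.x - prev) / np.maximum(np.abs(prev), 1e-12)) < 1e-4:
                break
    if best is None:
        return FitResult({}, {}, [], [], np.nan, np.nan, 0, converged=False,
                         message="all starts failed")
    cov, singular = _covariance(best)
    err = np.sqrt(np.maximum(np.diag(cov), 0.0))
    n_dof = max(curve.q.size - len(free), 1)
    chi2 = 2.0 * best.cost
    params = dict(zip(free, (float(v) for v in best.x)))
    stderr = dict(zip(free, (float(v) for v in err)))
    return FitResult(
        params=params,
        stderr=stderr,
        per_curve=[dict(params)],
        per_curve_stderr=[dict(stderr)],
        chi2=float(chi2),
        reduced_chi2=float(chi2 / n_dof),
        n_dof=n_dof,
        converged=bool(best.success),
        singular=singular,
        message=best.message,
    )


def fit_contrast_series(
    series: ContrastSeries,
    init: SANSModelParams,
    shared: tuple[str, ...] = DEFAULT_SHARED,
    fixed: frozenset[str] | set[str] = DEFAULT_FIXED,
    n_starts: int = 5,
) -> FitResult:
    """Simultaneous fit of all contrasts: geometry (and any other
    ``shared`` parameter) identical across curves, per-curve particle SLD,
    power-law amplitude and background free unless ``fixed``.

    The per-curve solvent SLD is computed from each curve's D2O fraction.
    """
    if len(series) < 2:
        raise ValueError("a simultaneous contrast fit needs at least 2 curves")
    fracs = series.d2o_fractions
    if any(np.isnan(fracs)):
        raise ValueError("every curve needs a D2O fraction tag")
    if len(set(fracs)) != len(fracs):
        raise ValueError("D2O fractions must be distinct")
    _valid_names(fixed)
    _valid_names(shared)
    shared_free = [n for n in shared if n not in fixed]
    per_free = [n for n in _PER_CURVE if n not in fixed and n not in shared]
    n_curves = len(series)
    names = list(shared_free)
    for i in range(n_curves):
        names += [f"{n}[{i}]" for n in per_free]

    base = [
        replace(init, sld_solvent=solvent_sld(f), d2o_fraction=f)
        for f in fracs
    ]
    x0, lo, hi = [], [], []
    for n in shared_free:
        x0.append(getattr(init, n))
        lo.append(_FITTABLE_BOUNDS[n][0])
        hi.append(_FITTABLE_BOUNDS[n][1])
    for i in range(n_curves):
        for n in per_free:
            v = getattr(init, n)
            if n == "sld_particle" and not np.isfinite(v):
                v = 0.5 * (base[i].sld_solvent + 2.0)
            x0.append(v)
            lo.append(_FITTABLE_BOUNDS[n][0])
            hi.append(_FITTABLE_BOUNDS[n][1])
    x0 = np.clip(np.array(x0, dtype=float), lo, hi)
    lo, hi = np.array(lo), np.array(hi)
    weights = [_weights(c) for c in series]

    ns, npc = len(shared_free), len(per_free)

    def params_for(x: np.ndarray, i: int) -> SANSModelParams:
        upd = dict(zip(shared_free, x[:ns]))
        off = ns + i * npc
        upd.update(dict(zip(per_free, x[off : off + npc])))
        return replace(base[i], **upd)

    # fixed-S inner fits inside a short self-consistent outer loop (see
    # fit_single_curve); the geometry is shared, so one S(q) per curve grid
    s_list = [structure_factor(c.q, params_for(x0, i))
              for i, c in enumerate(series)]

    def resid(x: np.ndarray) -> np.ndarray:
        out = []
        for i, curve in enumerate(series):
            model = composite_intensity(
                curve.q, params_for(x, i), s_of_q=s_list[i]
            )
            out.append((model - curve.intensity) * weights[i])
        return np.concatenate(out)

    best = None
    for start in _jitter_starts(x0, lo, hi, n_starts):
        try:
            res = least_squares(resid, start, bounds=(lo, hi), method="trf")
        except RuntimeError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is not None:
        # iterate S(q) to self-consistency with the fitted geometry
        for _ in range(4):
            prev = best.x.copy()
            s_list = [structure_factor(c.q, params_for(best.x, i))
                      for i, c in enumerate(series)]
            best = least_squares(resid, best.x, bounds=(lo, hi), method="trf")
            if np.max(np.abs(best.x - prev) / np.maximum(np.abs(prev), 1e-12)) < 1e-4:
                break
    if best is None:
        return FitResult({}, {}, [], [], np.nan, np.nan, 0, converged=False,
                         message="all starts failed")
    cov, singular = _covariance(best)
    err = np.sqrt(np.maximum(np.diag(cov), 0.0))
    n_points = sum(c.q.size for c in series)
    n_dof = max(n_points - len(x0), 1)
    chi2 = 2.0 * best.cost

    params = dict(zip(shared_free, (float(v) for v in best.x[:ns])))
    stderr = dict(zip(shared_free, (float(v) for v in err[:ns])))
    per_curve, per_curve_err = [], []
    for i in range(n_curves):
        off = ns + i * npc
        pc = dict(zip(per_free, (float(v) for v in best.x[off : off + npc])))
        pe = dict(zip(per_free, (float(v) for v in err[off : off + npc])))
        for n in _PER_CURVE:
            if n not in pc:
                pc[n] = float(getattr(base[i], n))
                pe[n] = 0.0
        pc["d2o_fraction"] = float(fracs[i])
        pc["sld_solvent"] = float(base[i].sld_solvent)
        per_curve.append(pc)
        per_curve_err.append(pe)
    _reconcile_sld_branches(per_curve)
    if singular:
        warnings.warn(
            "rank-deficient Jacobian at the optimum (a contrast-matched "
            "curve carries no SLD information?)",
            stacklevel=2,
        )
    return FitResult(
        params=params,
        stderr=stderr,
        per_curve=per_curve,
        per_curve_stderr=per_curve_err,
        chi2=float(chi2),
        reduced_chi2=float(chi2 / n_dof),
        n_dof=n_dof,
        converged=bool(best.success),
        singular=singular,
        message=best.message,
    )


def _reconcile_sld_branches(per_curve: list[dict[str, float]]) -> None:
    """Resolve the per-curve particle-SLD sign ambiguity.

    Intensity depends on contrast squared, so for each curve the mirrored
    SLD 2 * s - p (s = solvent SLD) fits exactly as well as p. The joint
    chi^2 cannot choose, but contrast variation can: the physical branch
    set makes particle SLD linear in solvent SLD with a slope (the water
    fraction) inside [0, 1]. Flip curves, in place, to the combination
    that satisfies that and maximises the regression r^2.
    """
    from itertools import product

    n = len(per_curve)
    if n < 2:
        return
    p = np.array([pc["sld_particle"] for pc in per_curve])
    s = np.array([pc["sld_solvent"] for pc in per_curve])
    if np.unique(s).size < 2:
        return
    best = None
    for flips in product((False, True), repeat=n):
        cand = np.where(flips, 2.0 * s - p, p)
        reg = stats.linregress(s, cand)
        physical = 0.0 <= reg.slope <= 1.0
        r2 = reg.rvalue**2 if np.isfinite(reg.rvalue) else 0.0
        # prefer physical slope, then fit quality, then fewer flips
        score = (physical, r2, -sum(flips))
        if best is None or score > best[0]:
            best = (score, cand)
    for pc, value in zip(per_curve, best[1]):
        pc["sld_particle"] = float(value)


# ----------------------------------------------------------------------
def water_fraction_from_slds(
    particle_slds, solvent_slds
) -> WaterFractionResult:
    """Ordinary least squares of particle SLD on solvent SLD.

    Slope = water volume fraction inside the particle; intercept =
    (1 - phi_water) * dry SLD. A slope outside [0, 1] is clipped and
    flagged rather than rejected.
    """
    p = np.asarray(particle_slds, dtype=float)
    s = np.asarray(solvent_slds, dtype=float)
    if p.shape != s.shape or p.ndim != 1:
        raise ValueError("particle and solvent SLD lists must match")
    if p.size < 2:
        raise ValueError("need at least 2 contrasts for the regression")
    if np.unique(s).size < 2:
        raise ValueError("solvent SLDs must be distinct")
    if p.size == 2:
        warnings.warn(
            "two-point regression: exact interpolation, no residual dof",
            stacklevel=2,
        )
    reg = stats.linregress(s, p)
    phi = float(reg.slope)
    clipped = not 0.0 <= phi <= 1.0
    phi_c = float(np.clip(phi, 0.0, 1.0))
    denom = 1.0 - phi_c
    sld_dry = float(reg.intercept / denom) if denom > 1e-9 else float("nan")
    return WaterFractionResult(
        phi_water=phi_c,
        sld_dry=sld_dry,
        r_squared=float(reg.rvalue**2),
        slope_stderr=float(reg.stderr) if np.isfinite(reg.stderr) else 0.0,
        clipped=clipped,
        n_points=int(p.size),
    )
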