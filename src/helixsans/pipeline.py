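"""Orchestration: configuration, reports, the two analysis pipelines and
the titration (pKa) fit.

The conformation pipeline chains helix-geometry fitting, H-bond
partitioning and hydration analysis over one trajectory; the SANS pipeline
chains power-law characterisation, the simultaneous multi-contrast fit and
the contrast-variation water-fraction regression. Both consume a flat
key-value configuration (unknown keys rejected) and emit a JSON-serialisable
report that echoes the resolved configuration, so a rerun with the same
config and seed reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import __version__
from .hbond_analysis import (
    DEFAULT_ANGLE_CUTOFF_DEG,
    DEFAULT_DIST_CUTOFF_NM,
    count_dangling_backbone_groups,
    per_residue_hbond_stats,
)
from .helix_geometry import DEFAULT_N_EXCLUDE, fit_helix, rmsd_time_trace
from .hydration_analysis import (
    DEFAULT_BIN_WIDTH_NM,
    DEFAULT_DEPLETION_THRESHOLD,
    DEFAULT_N_BLOCKS,
    block_average_rdf,
    depletion_radius,
)
from .peptide_model import LigandKind, build_topology
from .sans_fit import (
    DEFAULT_POWERLAW_WINDOW,
    fit_contrast_series,
    fit_powerlaw_exponent,
    water_fraction_from_slds,
)
from .sans_model import ContrastSeries, SANSModelParams, solvent_sld
from .synthetic_data import (
    DEFAULT_SLD_DRY,
    TitrationCurve,
    generate_trajectory,
    read_sans_curve,
    read_trajectory_pdb,
    simulate_contrast_series,
)

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "Report",
    "run_conformation_pipeline",
    "run_sans_pipeline",
    "fit_pka",
    "PkaFit",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


# schema: key -> (type, default); None default means "required or unused"
_CONFORMATION_SCHEMA: dict[str, tuple[type, Any]] = {
    "kind": (str, "stable_helix"),
    "n_residues": (int, 10),
    "ligand": (str, "triazole"),
    "protonated": (bool, True),
    "n_frames": (int, 50),
    "time_step_ns": (float, 1.0),
    "seed": (int, 0),
    "amplitude": (float, 0.025),
    "n_waters": (int, 2000),
    "box_edge": (float, 6.0),
    "depletion_radius": (float, 0.0),
    "trajectory_pdb": (str, ""),
    "n_exclude": (int, DEFAULT_N_EXCLUDE),
    "dist_cutoff": (float, DEFAULT_DIST_CUTOFF_NM),
    "angle_cutoff": (float, DEFAULT_ANGLE_CUTOFF_DEG),
    "bin_width": (float, DEFAULT_BIN_WIDTH_NM),
    "n_blocks": (int, DEFAULT_N_BLOCKS),
    "depletion_threshold": (float, DEFAULT_DEPLETION_THRESHOLD),
    "run_helix": (bool, True),
    "run_hbonds": (bool, True),
    "run_hydration": (bool, True),
}

_SANS_SCHEMA: dict[str, tuple[type, Any]] = {
    "preset": (str, "pH2"),
    "phi_water": (float, float("nan")),
    "sld_dry": (float, DEFAULT_SLD_DRY),
    "d2o_fractions": (str, "1.0,0.75,0.5"),
    "relative_noise": (float, 0.02),
    "seed": (int, 0),
    "series_dir": (str, ""),
    "init_radius_a": (float, 15.0),
    "init_length_a": (float, 60.0),
    "init_sld_particle": (float, 3.0),
    "init_powerlaw_amplitude": (float, 1e-6),
    "init_powerlaw_exponent": (float, 3.55),
    "init_background": (float, 2e-3),
    "volfraction": (float, 0.005),
    "charge": (float, 20.0),
    "screening_length_a": (float, 30.0),
    "powerlaw_window_lo": (float, DEFAULT_POWERLAW_WINDOW[0]),
    "powerlaw_window_hi": (float, DEFAULT_POWERLAW_WINDOW[1]),
    "n_starts": (int, 5),
}


@dataclass
class PipelineConfig:
    """Validated flat configuration for one pipeline run."""

    values: dict[str, Any]
    schema_name: str

    @classmethod
    def conformation(cls, **overrides) -> "PipelineConfig":
        return cls._build(_CONFORMATION_SCHEMA, "conformation", overrides)

    @classmethod
    def sans(cls, **overrides) -> "PipelineConfig":
        return cls._build(_SANS_SCHEMA, "sans", overrides)

    @classmethod
    def _build(cls, schema, name, overrides) -> "PipelineConfig":
        unknown = set(overrides) - set(schema)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        vals = {}
        for key, (typ, default) in schema.items():
            raw = overrides.get(key, default)
            try:
                vals[key] = _coerce(raw, typ)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"bad value for {key!r}: {raw!r}") from exc
        return cls(vals, name)

    @classmethod
    def from_file(cls, path: str, schema_name: str) -> "PipelineConfig":
        """Flat ``key = value`` file, '#' comments."""
        overrides: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{ln}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                overrides[key] = val
        if schema_name == "conformation":
            return cls.conformation(**overrides)
        if schema_name == "sans":
            return cls.sans(**overrides)
        raise ConfigError(f"unknown schema {schema_name!r}")

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _coerce(raw: Any, typ: type) -> Any:
    if typ is bool:
        if isinstance(raw, bool):
            return raw
        if str(raw).lower() in ("true", "1", "yes", "on"):
            return True
        if str(raw).lower() in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"not a boolean: {raw!r}")
    return typ(raw)


@dataclass
class Report:
    """Serializable per-stage results with provenance."""

    pipeline: str
    config: dict[str, Any]
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict[str, Any] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent,
                          sort_keys=True, default=_jsonify)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


# ----------------------------------------------------------------------
def run_conformation_pipeline(config: PipelineConfig) -> Report:
    """Helix geometry -> H-bond partition -> hydration, over one
    trajectory (synthetic unless ``trajectory_pdb`` points at a file).
    Stage failures are recorded in the report, not raised."""
    if config.schema_name != "conformation":
        raise ConfigError("conformation pipeline needs a conformation config")
    c = config.values
    model = build_topology(
        c["n_residues"], LigandKind.coerce(c["ligand"]), c["protonated"]
    )
    if c["trajectory_pdb"]:
        import os

        if not os.path.exists(c["trajectory_pdb"]):
            raise ConfigError(
                f"trajectory file not found: {c['trajectory_pdb']!r}"
            )
        traj = read_trajectory_pdb(c["trajectory_pdb"], model,
                                   time_step_ns=c["time_step_ns"])
    else:
        traj = generate_trajectory(
            model,
            c["kind"],
            c["n_frames"],
            c["time_step_ns"],
            seed=c["seed"],
            amplitude=c["amplitude"],
            n_waters=c["n_waters"],
            box_edge=c["box_edge"],
            depletion_radius=c["depletion_radius"],
        )
    report = Report(
        pipeline="conformation",
        config=dict(c),
        config_hash=config.hash(),
        seed=c["seed"],
    )
    if c["run_helix"]:
        try:
            last = traj.frames[-1].conformation
            fit = fit_helix(last.calpha(), n_exclude=c["n_exclude"])
            trace = rmsd_time_trace(traj, n_exclude=c["n_exclude"])
            report.stages["helix"] = {
                "final_fit": fit.to_dict(),
                "rmsd_trace": trace,
                "rmsd_mean_nm": float(np.nanmean(trace[:, 1])),
                "rmsd_std_nm": float(np.nanstd(trace[:, 1])),
                "helical": bool(
                    fit.rmsd_helix_nm <= 0.08 and not fit.degenerate
                ),
            }
        except Exception as exc:  # recorded, not fatal
            report.failures["helix"] = str(exc)
    if c["run_hbonds"]:
        try:
            stats = per_residue_hbond_stats(
                traj, model, n_exclude=0,
                dist_cutoff=c["dist_cutoff"], angle_cutoff=c["angle_cutoff"],
            )
            dang = count_dangling_backbone_groups(
                traj.frames[-1].conformation, model,
                dist_cutoff=c["dist_cutoff"], angle_cutoff=c["angle_cutoff"],
            )
            report.stages["hbonds"] = {
                "per_residue_mean": stats.mean,
                "per_residue_std": stats.std,
                "dangling_nh": dang[0],
                "dangling_co": dang[1],
            }
        except Exception as exc:
            report.failures["hbonds"] = str(exc)
    if c["run_hydration"]:
        try:
            rdf = block_average_rdf(
                traj, model, n_blocks=min(c["n_blocks"], len(traj)),
                bin_width=c["bin_width"],
            )
            report.stages["hydration"] = {
                "r_nm": rdf.bin_centers,
                "g": rdf.g,
                "stderr": rdf.stderr,
                "depletion_radius_nm": depletion_radius(
                    rdf, c["depletion_threshold"]
                ),
            }
        except Exception as exc:
            report.failures["hydration"] = str(exc)
    return report


def run_sans_pipeline(config: PipelineConfig) -> Report:
    """Power-law fit -> simultaneous contrast fit -> SLD regression ->
    water fraction."""
    import glob
    import os

    if config.schema_name != "sans":
        raise ConfigError("SANS pipeline needs a sans config")
    c = config.values
    if c["series_dir"]:
        paths = sorted(glob.glob(os.path.join(c["series_dir"], "*.dat")))
        curves = [read_sans_curve(p) for p in paths]
        if len(curves) < 2:
            raise ConfigError(
                f"need at least 2 curves in {c['series_dir']!r}, "
                f"found {len(curves)}"
            )
        series = ContrastSeries(curves=curves)
    else:
        geometry: dict | str = c["preset"]
        phi = c["phi_water"]
        series = simulate_contrast_series(
            geometry,
            phi_water=None if np.isnan(phi) else phi,
            sld_dry=c["sld_dry"],
            d2o_fractions=[float(x) for x in c["d2o_fractions"].split(",")],
            relative_noise=c["relative_noise"],
            seed=c["seed"],
        )
    report = Report(
        pipeline="sans",
        config=dict(c),
        config_hash=config.hash(),
        seed=c["seed"],
    )
    window = (c["powerlaw_window_lo"], c["powerlaw_window_hi"])
    powerlaw = []
    for curve in series:
        try:
            n, se = fit_powerlaw_exponent(curve, window)
            powerlaw.append(
                {"d2o_fraction": curve.d2o_fraction, "exponent": n,
                 "stderr": se}
            )
        except ValueError as exc:
            report.failures.setdefault("powerlaw", str(exc))
    report.stages["powerlaw"] = powerlaw

    init = SANSModelParams(
        radius_a=c["init_radius_a"],
        length_a=c["init_length_a"],
        sld_particle=c["init_sld_particle"],
        sld_solvent=solvent_sld(1.0),
        volfraction=c["volfraction"],
        charge=c["charge"],
        screening_length_a=c["screening_length_a"],
        powerlaw_amplitude=c["init_powerlaw_amplitude"],
        powerlaw_exponent=c["init_powerlaw_exponent"],
        background=c["init_background"],
    )
    fit = fit_contrast_series(series, init, n_starts=c["n_starts"])
    report.stages["joint_fit"] = {
        "params": fit.params,
        "stderr": fit.stderr,
        "per_curve": fit.per_curve,
        "reduced_chi2": fit.reduced_chi2,
        "converged": fit.converged,
        "singular": fit.singular,
    }
    if fit.converged:
        wf = water_fraction_from_slds(
            fit.particle_slds,
            [pc["sld_solvent"] for pc in fit.per_curve],
        )
        report.stages["water_fraction"] = dataclasses.asdict(wf)
    else:
        report.failures["water_fraction"] = "joint fit did not converge"
    return report


# ----------------------------------------------------------------------
@dataclass
class PkaFit:
    """Henderson-Hasselbalch fit of a titration curve."""

    pka: float
    stderr: float
    rmse: float
    converged: bool
    flags: list[str] = field(default_factory=list)


def fit_pka(curve: TitrationCurve) -> PkaFit:
    """Least-squares fit of f(pH) = 1 / (1 + 10^(pH - pKa)).

    Requires at least 4 points; flat data (no transition in range) and
    fractions that increase with pH are flagged.
    """
    from scipy.optimize import curve_fit

    ph = curve.ph
    frac = curve.fraction
    if ph.size < 4:
        raise ValueError("need at least 4 titration points")
    flags: list[str] = []
    span = float(frac.max() - frac.min())
    if span < 0.2:
        flags.append("no_transition")
    slope = np.polyfit(ph, frac, 1)[0]
    if slope > 0:
        flags.append("non_physical_increasing")

    def model(x, pka):
        return 1.0 / (1.0 + 10.0 ** (x - pka))

    p0 = float(np.interp(0.5, frac[::-1], ph[::-1])) if span > 0 else float(
        np.median(ph)
    )
    try:
        popt, pcov = curve_fit(model, ph, frac, p0=[p0], maxfev=10000)
        resid = frac - model(ph, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
        return PkaFit(float(popt[0]), stderr, rmse,
                      converged="no_transition" not in flags
                      and "non_physical_increasing" not in flags,
                      flags=flags)
    except RuntimeError as exc:
        return PkaFit(float("nan"), float("inf"), float("inf"), False,
                      flags=flags + [f"fit_failed: {exc}"])
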