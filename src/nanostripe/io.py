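"""Trajectory and configuration I/O.

Trajectories are exchanged as standard XYZ text (atom-count line, comment
line carrying the frame time, one ``C x y z`` record per bead with z = 0
for the planar model), accompanied by a JSON sidecar holding provenance.
Run configuration is a TOML document with sections [chain], [surface],
[field], [scenario] and [analysis]; unknown keys are rejected by name so
typos never silently fall back to defaults.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np

from .model import ChainParams, FieldSpec, SurfacePattern, UnitsConvention
from .simulate import Scenario, Trajectory, _SCENARIO_DEFAULTS

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "XYZParseError",
    "ConfigError",
    "RunConfig",
    "load_config",
]

_UNITS = UnitsConvention()


class XYZParseError(ValueError):
    """Malformed XYZ input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")


def write_trajectory(path, traj: Trajectory, element: str = "C") -> None:
    """Write a trajectory as multi-frame XYZ plus a ``<path>.json``
    provenance sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            fh.write(f"t= {traj.times[k]:.9g} ns\n")
            for x, y in traj.positions[k]:
                fh.write(f"{element} {x:.9f} {y:.9f} 0.0\n")
    sidecar = {
        "format": "nanostripe-xyz",
        "dt_between_frames_ns": float(traj.dt_between_frames),
        "n_frames": int(traj.n_frames),
        "n_beads": int(traj.n_beads),
        "provenance": _jsonable(traj.provenance),
    }
    with open(path.with_name(path.name + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_trajectory(path) -> Trajectory:
    """Read a multi-frame XYZ trajectory (with optional JSON sidecar).

    Frame times are taken from ``t= <value>`` comment lines when present,
    otherwise from the sidecar frame interval.  A malformed or truncated
    file raises :class:`XYZParseError` naming the line and the last
    complete frame.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()

    frames: list[np.ndarray] = []
    times: list[float] = []
    ln = 0
    while ln < len(lines):
        if lines[ln].strip() == "":
            ln += 1
            continue
        header_line = ln + 1
        try:
            n_at = int(lines[ln].strip())
        except ValueError:
            raise XYZParseError(
                f"expected an atom count, got {lines[ln]!r} "
                f"(last complete frame: {len(frames)})", header_line,
            ) from None
        if ln + 1 + n_at >= len(lines) + 1 and ln + 1 >= len(lines):
            raise XYZParseError(
                f"missing comment line (last complete frame: {len(frames)})",
                header_line + 1,
            )
        comment = lines[ln + 1]
        t = None
        for tok_i, tok in enumerate(parts := comment.split()):
            if tok in ("t=", "time=") and tok_i + 1 < len(parts):
                try:
                    t = float(parts[tok_i + 1])
                except ValueError:
                    pass
        coords = np.empty((n_at, 2))
        for i in range(n_at):
            idx = ln + 2 + i
            if idx >= len(lines):
                raise XYZParseError(
                    f"frame truncated after {i} of {n_at} atoms "
                    f"(last complete frame: {len(frames)})", idx + 1,
                )
            toks = lines[idx].split()
            if len(toks) < 4:
                raise XYZParseError(
                    f"expected 'element x y z', got {lines[idx]!r} "
                    f"(last complete frame: {len(frames)})", idx + 1,
                )
            try:
                coords[i] = float(toks[1]), float(toks[2])
            except ValueError:
                raise XYZParseError(
                    f"non-numeric coordinate in {lines[idx]!r} "
                    f"(last complete frame: {len(frames)})", idx + 1,
                ) from None
        frames.append(coords)
        times.append(t if t is not None else float(len(times)))
        ln += 2 + n_at

    if not frames:
        raise XYZParseError("empty trajectory file", 1)

    sidecar_path = path.with_name(path.name + ".json")
    provenance: dict = {}
    dt = None
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sc = json.load(fh)
        provenance = sc.get("provenance", {})
        dt = sc.get("dt_between_frames_ns")
    times_arr = np.asarray(times)
    if len(frames) > 1:
        diffs = np.diff(times_arr)
        dt_frames = float(np.median(diffs))
        if dt_frames <= 0:
            dt_frames = dt if dt else 1.0
            times_arr = np.arange(len(frames)) * dt_frames
        elif np.allclose(diffs, dt_frames, rtol=1e-5, atol=1e-12):
            # frame times in the file are rounded to the comment-line
            # precision; rebuild them on an exactly uniform grid
            if dt is not None:
                dt_frames = float(dt)
            times_arr = times_arr[0] + np.arange(len(frames)) * dt_frames
    else:
        dt_frames = dt if dt else 1.0
    return Trajectory(
        positions=np.stack(frames),
        times=times_arr,
        dt_between_frames=dt_frames,
        provenance=provenance,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# TOML run configuration

class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad value...)."""


_CHAIN_KEYS = {
    "n_beads", "bond_length_a", "target_lp", "bond_stiffness",
    "bend_stiffness_kappa", "excluded_volume", "ev_diameter", "ev_strength",
    "ev_distant_min_sep", "ev_distant_diameter", "ev_distant_strength",
    "per_bead_charge", "per_bead_friction",
}
_SURFACE_KEYS = {
    "geometry", "delta_eps_kcal_per_mol", "base_eps_kcal_per_mol",
    "stripe_width_w", "smoothing_delta",
}
_FIELD_KEYS = {"field_E", "voltage_V", "box_length_Lx"}
_SCENARIO_KEYS = {
    "name", "seed", "initial_conformation", "placement", "n_steps", "dt",
    "sample_every", "equilibration_fraction",
}
_ANALYSIS_KEYS = {
    "lp_fit_min", "lp_fit_max", "max_sep", "msd_max_lag_frames",
    "n_backbone_charges", "bjerrum_length",
}
_SECTIONS = {
    "chain": _CHAIN_KEYS,
    "surface": _SURFACE_KEYS,
    "field": _FIELD_KEYS,
    "scenario": _SCENARIO_KEYS,
    "analysis": _ANALYSIS_KEYS,
}


@dataclass
class RunConfig:
    """Fully resolved configuration for one simulation/analysis run."""

    params: ChainParams
    pattern: SurfacePattern
    field: FieldSpec
    scenario: Optional[Scenario]
    analysis: dict = dc_field(default_factory=dict)
    raw: dict = dc_field(default_factory=dict)


def load_config(path, seed: Optional[int] = None) -> RunConfig:
    """Load and validate a TOML run configuration.

    ``seed`` overrides any seed in the file (command-line precedence).
    Unknown sections or keys raise :class:`ConfigError` naming the
    offender.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return build_config(doc, seed=seed)


def build_config(doc: dict, seed: Optional[int] = None) -> RunConfig:
    for section in doc:
        if section not in _SECTIONS:
            raise ConfigError(f"unknown config section [{section}]")
        for key in doc[section]:
            if key not in _SECTIONS[section]:
                raise ConfigError(f"unknown key '{key}' in section [{section}]")

    chain_kw = dict(doc.get("chain", {}))
    params = ChainParams(**chain_kw)

    surf_kw = dict(doc.get("surface", {}))
    if "delta_eps_kcal_per_mol" in surf_kw:
        surf_kw["delta_eps"] = _UNITS.kcal_per_mol_to_kBT(
            surf_kw.pop("delta_eps_kcal_per_mol"))
    if "base_eps_kcal_per_mol" in surf_kw:
        surf_kw["base_eps"] = _UNITS.kcal_per_mol_to_kBT(
            surf_kw.pop("base_eps_kcal_per_mol"))
    pattern = SurfacePattern(**surf_kw)

    field_kw = dict(doc.get("field", {}))
    if "voltage_V" in field_kw or "box_length_Lx" in field_kw:
        if not {"voltage_V", "box_length_Lx"} <= set(field_kw):
            raise ConfigError(
                "voltage_V and box_length_Lx must be given together")
        fspec = FieldSpec.from_voltage(field_kw["voltage_V"],
                                       field_kw["box_length_Lx"])
        if "field_E" in field_kw and not np.isclose(
                field_kw["field_E"], fspec.field_E, rtol=1e-12):
            raise ConfigError(
                f"field_E={field_kw['field_E']} inconsistent with "
                f"voltage_V/box_length_Lx={fspec.field_E}")
    else:
        fspec = FieldSpec(**field_kw)

    scenario = None
    if "scenario" in doc:
        sc_kw = dict(doc["scenario"])
        name = sc_kw.pop("name", None)
        if name is None:
            raise ConfigError("[scenario] requires a 'name' key")
        if name not in _SCENARIO_DEFAULTS:
            raise ConfigError(f"unknown scenario name '{name}'")
        file_seed = sc_kw.pop("seed", None)
        use_seed = seed if seed is not None else file_seed
        if use_seed is None:
            raise ConfigError("a seed is required (config [scenario] or --seed)")
        if "placement" in sc_kw:
            sc_kw["placement"] = tuple(sc_kw["placement"])
        scenario = Scenario.preset(
            name, int(use_seed), params=params, pattern=pattern, field=fspec,
            **sc_kw,
        )

    return RunConfig(
        params=params, pattern=pattern, field=fspec, scenario=scenario,
        analysis=dict(doc.get("analysis", {})), raw=doc,
    )
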