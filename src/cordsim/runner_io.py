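"""Run configuration (YAML), reference fixtures and table serialization.

A run config is a YAML mapping; every field is optional and defaults to the
baseline cord simulation (Table-of-defaults parameters, profile pk1, 72 h):

.. code-block:: yaml

    preset: baseline            # or modified_vasculature / strong_binding
    params: {kv: 2.8e-5}        # raw parameter overrides
    profile: {kind: pk3, level: 0.926, duration: 10800}
    variant: cord               # cord | clamped | sphere | wellmixed
    t_max_h: 72
    solver: {rtol: 1.0e-8, atol: 1.0e-12}
    outdir: results

Outputs are plain CSV tables (full float precision, deterministic) with a
JSON sidecar recording parameters, tolerances and solver statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dynamics import WellMixedSystem, cord_unpack
from .geometry import build_cord_grid, build_sphere_grid
from .params import ModelParams, ParameterError, apply_preset, default_params
from .pk_profiles import PKProfile, make_profile
from .simulate import SimulationResult, run

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "config_from_dict",
    "make_fixture",
    "run_config",
    "write_tables",
    "read_tables",
]


class ConfigError(ValueError):
    """Invalid run configuration."""


_VALID_KEYS = {
    "preset",
    "params",
    "profile",
    "variant",
    "t_max_h",
    "solver",
    "outdir",
    "seed",
    "sweep",
    "dose",
    "survival",
    "spheroid",
    "sphere_radius",
}
_VALID_SOLVER_KEYS = {"rtol", "atol", "atol_exposure"}
_VALID_PROFILE_KEYS = {"kind", "dose", "level", "duration", "times", "levels"}


@dataclass
class RunConfig:
    """Validated, fully defaulted description of one experiment."""

    params: ModelParams
    profile: PKProfile
    variant: str = "cord"
    t_max: float = 72 * 3600.0
    rtol: float = 1e-8
    atol: float = 1e-12
    atol_exposure: float = 1e-10
    outdir: str = "results"
    sphere_radius: float | None = None
    seed: int | None = None  # reserved: the model itself is deterministic
    extras: dict[str, Any] = field(default_factory=dict)


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    """Build a RunConfig from a parsed mapping, validating keys and types."""
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _VALID_KEYS
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)}; valid: {sorted(_VALID_KEYS)}"
        )
    base = default_params()
    if "preset" in raw:
        base = apply_preset(raw["preset"], base)
    overrides = raw.get("params", {})
    if not isinstance(overrides, dict):
        raise ConfigError("'params' must be a mapping of parameter overrides")
    try:
        params = base.replace(**overrides) if overrides else base
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc

    prof_spec = raw.get("profile", {"kind": "pk1"})
    if isinstance(prof_spec, str):
        prof_spec = {"kind": prof_spec}
    if not isinstance(prof_spec, dict) or "kind" not in prof_spec:
        raise ConfigError("'profile' must name a kind (pk1|pk2|pk3|custom)")
    unknown = set(prof_spec) - _VALID_PROFILE_KEYS
    if unknown:
        raise ConfigError(f"unknown profile key(s) {sorted(unknown)}")
    try:
        profile = make_profile(**prof_spec)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid profile spec: {exc}") from exc

    solver = raw.get("solver", {})
    if not isinstance(solver, dict) or set(solver) - _VALID_SOLVER_KEYS:
        raise ConfigError(f"'solver' accepts keys {sorted(_VALID_SOLVER_KEYS)}")

    t_max_h = raw.get("t_max_h", 72.0)
    if not isinstance(t_max_h, (int, float)) or not t_max_h > 0:
        raise ConfigError("'t_max_h' must be a positive number of hours")

    variant = raw.get("variant", "cord")
    if variant not in ("cord", "clamped", "sphere", "wellmixed"):
        raise ConfigError(f"unknown variant {variant!r}")

    extras = {k: raw[k] for k in ("sweep", "dose", "survival", "spheroid") if k in raw}
    return RunConfig(
        params=params,
        profile=profile,
        variant=variant,
        t_max=float(t_max_h) * 3600.0,
        rtol=float(solver.get("rtol", 1e-8)),
        atol=float(solver.get("atol", 1e-12)),
        atol_exposure=float(solver.get("atol_exposure", 1e-10)),
        outdir=str(raw.get("outdir", "results")),
        sphere_radius=raw.get("sphere_radius"),
        seed=raw.get("seed"),
        extras=extras,
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config file."""
    path = Path(path)
    with path.open() as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(raw)


def run_config(cfg: RunConfig) -> SimulationResult:
    """Execute the single simulation a RunConfig describes."""
    grid = None
    if cfg.variant == "sphere":
        radius = cfg.sphere_radius if cfg.sphere_radius is not None else 10 * cfg.params.d
        grid = build_sphere_grid(float(radius), cfg.params.d)
    return run(
        cfg.variant,
        cfg.params,
        cfg.profile,
        cfg.t_max,
        grid=grid,
        rtol=cfg.rtol,
        atol=cfg.atol,
        atol_exposure=cfg.atol_exposure,
    )


# ---------------------------------------------------------------------------
# fixtures


def make_fixture(kind: str) -> dict[str, Any]:
    """Small ready-to-run model specs used by the test-suite and examples.

    * ``tiny_cord``  — 3 shells × 4 discs at baseline rates;
    * ``wellmixed``  — the closed three-pool system on a unit tissue volume
      (V1 = delta1, V2 = delta2, a = alpha);
    * ``sphere_small`` — a 5-shell spheroid.
    """
    p = default_params()
    if kind == "tiny_cord":
        tiny = p.replace(n=3, m_discs=4)
        return {"variant": "cord", "params": tiny, "grid": build_cord_grid(tiny)}
    if kind == "wellmixed":
        system = WellMixedSystem(V1=p.delta1, V2=p.delta2, a=p.alpha)
        return {"variant": "wellmixed", "params": p, "system": system}
    if kind == "sphere_small":
        return {"variant": "sphere", "params": p, "grid": build_sphere_grid(5 * p.d, p.d)}
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# output tables


def _result_frames(result: SimulationResult) -> dict[str, pd.DataFrame]:
    f = result.exposure_field()
    if result.variant in ("cord", "clamped"):
        g = result.grid
        final = result.final_state()
        if result.variant == "cord":
            C1, C2, C3, Cv = cord_unpack(final, g)
        else:
            C1, C2, C3 = cord_unpack(final, g, vessel=False)
            Cv = None
        ii, jj = np.meshgrid(np.arange(g.n), np.arange(g.m), indexing="ij")
        tissue = pd.DataFrame(
            {
                "shell": ii.ravel() + 1,
                "disc": jj.ravel() + 1,
                "r_um": (g.r_centres[:, None] * np.ones((1, g.m))).ravel() * 1e6,
                "z_um": (np.ones((g.n, 1)) * g.z_centres[None, :]).ravel() * 1e6,
                "C1_uM": C1.ravel(),
                "C2_uM": C2.ravel(),
                "C3_uM": C3.ravel(),
                "E1_uMh": f.E1.ravel(),
                "E2_uMh": f.E2.ravel(),
                "E3_uMh": f.E3.ravel(),
            }
        )
        frames = {"tissue": tissue}
        if Cv is not None:
            frames["vessel"] = pd.DataFrame(
                {
                    "disc": np.arange(g.m) + 1,
                    "z_um": g.z_centres * 1e6,
                    "Cv_uM": Cv,
                    "Ev_uMh": f.Ev,
                }
            )
        return frames
    if result.variant == "sphere":
        g = result.grid
        n = g.n
        final = result.final_state()
        return {
            "shells": pd.DataFrame(
                {
                    "shell": np.arange(n) + 1,
                    "r_um": (np.arange(n) + 0.5) * g.d * 1e6,
                    "C1_uM": final[:n],
                    "C2_uM": final[n : 2 * n],
                    "C3_uM": final[2 * n :],
                    "E1_uMh": f.E1,
                    "E2_uMh": f.E2,
                    "E3_uMh": f.E3,
                }
            )
        }
    final = result.final_state()
    return {
        "wellmixed": pd.DataFrame(
            {
                "C1_uM": [final[0]],
                "C2_uM": [final[1]],
                "C3_uM": [final[2]],
                "E1_uMh": [f.E1],
                "E2_uMh": [f.E2],
                "E3_uMh": [f.E3],
            }
        )
    }


def write_tables(result: SimulationResult, outdir: str | Path) -> list[Path]:
    """Write CSV tables plus a JSON metadata sidecar; returns written paths.

    Floats are written with ``repr`` precision so re-reading reproduces the
    values bit-for-bit; identical runs produce byte-identical files.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for name, frame in _result_frames(result).items():
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
        meta = {k: v for k, v in result.metadata.items() if not k.startswith("_")}
        meta["t_max_h"] = result.t_max / 3600.0
        meta_path = outdir / "meta.json"
        meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        written.append(meta_path)
    except OSError as exc:
        raise OSError(f"cannot write results under {outdir}: {exc}") from exc
    return written


def read_tables(outdir: str | Path) -> dict[str, pd.DataFrame | dict]:
    """Read back tables written by :func:`write_tables`, bit-for-bit.

    Uses round-trip float parsing so the values equal the written ones
    exactly; the JSON sidecar is returned under the key ``meta``.
    """
    outdir = Path(outdir)
    out: dict[str, pd.DataFrame | dict] = {}
    for path in sorted(outdir.glob("*.csv")):
        out[path.stem] = pd.read_csv(path, float_precision="round_trip")
    meta_path = outdir / "meta.json"
    if meta_path.exists():
        out["meta"] = json.loads(meta_path.read_text())
    return out
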