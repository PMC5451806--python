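"""Model parameter set for the tumour-cord drug-transport model.

The baseline values describe doxorubicin transport in a cylindrical cord of
tumour tissue (9 concentric cell-layer shells of 20 μm around a 16 μm-radius
vessel, 25 axial cell-layer discs). All lengths are in metres, times in
seconds and concentrations in μM; exposures are converted to μM·h only at
the reporting boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "ModelParams",
    "ParameterError",
    "TABLE_DEFAULTS",
    "PRESETS",
    "derive_params",
    "default_params",
    "apply_preset",
]


class ParameterError(ValueError):
    """Raised when a parameter value or combination is physically invalid."""


#: Baseline parameter values (SI units; concentrations in μM).
TABLE_DEFAULTS: dict[str, float | int] = {
    "l": 1.6e-5,        # vessel radius, m
    "L_r": 1.96e-4,     # cord radius (vessel + 9 cell layers), m
    "L_z": 5.0e-4,      # cord length (25 cell layers), m
    "r_cell": 1.0e-5,   # cell radius, m
    "d": 2.0e-5,        # compartment edge length d_r = d_z, m
    "n": 9,             # radial shells
    "m_discs": 25,      # axial discs
    "delta": 0.0625,    # extracellular:intracellular volume ratio V1/V2
    "alpha": 1.94028e5, # membrane surface : tissue volume ratio, 1/m
    "k0": 2.5e-6,       # intercellular permeability, m/s
    "k1": 1.0e-6,       # transmembrane permeability, m/s
    "k2": 0.90e-6,      # binding rate, 1/(μM·s)
    "k_m2": 14.0e-6,    # unbinding rate, 1/s
    "kv": 2.8e-6,       # vessel-wall permeability, m/s
    "C0": 2.6e3,        # binding-site concentration, μM
    "lam": 1.0e-3,      # flow velocity in vessel, m/s
}

_RAW_FIELDS = tuple(TABLE_DEFAULTS)
_GEOM_RTOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Validated parameter set, including derived quantities.

    Derived fields: ``beta = k_m2/k2`` (μM), ``D_diff = 2*k0*r_cell`` (m²/s)
    and the tissue volume fractions ``delta1 = delta/(1+delta)``
    (extracellular) and ``delta2 = 1/(1+delta)`` (intracellular), so that
    ``delta1/delta2 = V1/V2 = delta`` and ``delta1 + delta2 = 1``.
    """

    l: float
    L_r: float
    L_z: float
    r_cell: float
    d: float
    n: int
    m_discs: int
    delta: float
    alpha: float
    k0: float
    k1: float
    k2: float
    k_m2: float
    kv: float
    C0: float
    lam: float
    beta: float
    D_diff: float
    delta1: float
    delta2: float

    def __post_init__(self) -> None:
        for name in _RAW_FIELDS:
            value = getattr(self, name)
            if not value > 0:
                raise ParameterError(f"parameter {name!r} must be > 0, got {value!r}")
        if self.n != int(self.n) or self.m_discs != int(self.m_discs):
            raise ParameterError("n and m_discs must be integers")
        if abs(self.l + self.n * self.d - self.L_r) > _GEOM_RTOL * self.L_r:
            raise ParameterError(
                f"geometry mismatch: l + n*d = {self.l + self.n * self.d!r} "
                f"does not equal L_r = {self.L_r!r}"
            )
        if abs(self.m_discs * self.d - self.L_z) > _GEOM_RTOL * self.L_z:
            raise ParameterError(
                f"geometry mismatch: m_discs*d = {self.m_discs * self.d!r} "
                f"does not equal L_z = {self.L_z!r}"
            )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, float | int]:
        """Raw (underived) parameter values; ``derive_params`` round-trips."""
        return {name: getattr(self, name) for name in _RAW_FIELDS}

    def replace(self, **overrides: float | int) -> "ModelParams":
        """New parameter set with raw fields replaced and derived fields rebuilt.

        Changing the vessel radius ``l`` or shell size/count keeps the cord
        closure l + n*d = L_r by recomputing L_r and L_z unless they are
        overridden explicitly.
        """
        raw = self.to_dict()
        unknown = set(overrides) - set(raw)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        geom_touched = {"l", "d", "n", "m_discs"} & set(overrides)
        raw.update(overrides)
        if geom_touched and "L_r" not in overrides:
            raw["L_r"] = raw["l"] + raw["n"] * raw["d"]
        if geom_touched and "L_z" not in overrides:
            raw["L_z"] = raw["m_discs"] * raw["d"]
        return derive_params(raw)

    def content_hash(self) -> str:
        """Stable hash of the raw parameter values (for run provenance)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def derive_params(raw_table: Mapping[str, float | int]) -> ModelParams:
    """Build a validated :class:`ModelParams` from raw named values.

    Missing entries fall back to the baseline defaults; the derived
    quantities beta, D_diff, delta1 and delta2 are always recomputed from
    the raw values. The membrane-surface:tissue-volume ratio ``alpha`` is
    taken verbatim (it is an independently estimated histological quantity).
    """
    unknown = set(raw_table) - set(_RAW_FIELDS)
    if unknown:
        raise ParameterError(
            f"unknown parameter(s): {sorted(unknown)}; valid: {sorted(_RAW_FIELDS)}"
        )
    merged: dict[str, float | int] = {**TABLE_DEFAULTS, **raw_table}
    for name in _RAW_FIELDS:
        value = merged[name]
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ParameterError(f"parameter {name!r} must be numeric, got {value!r}")
        if not value > 0:
            raise ParameterError(f"parameter {name!r} must be > 0, got {value!r}")
    n = int(merged["n"])
    m_discs = int(merged["m_discs"])
    if n != merged["n"] or m_discs != merged["m_discs"]:
        raise ParameterError("n and m_discs must be positive integers")
    delta = float(merged["delta"])
    return ModelParams(
        l=float(merged["l"]),
        L_r=float(merged["L_r"]),
        L_z=float(merged["L_z"]),
        r_cell=float(merged["r_cell"]),
        d=float(merged["d"]),
        n=n,
        m_discs=m_discs,
        delta=delta,
        alpha=float(merged["alpha"]),
        k0=float(merged["k0"]),
        k1=float(merged["k1"]),
        k2=float(merged["k2"]),
        k_m2=float(merged["k_m2"]),
        kv=float(merged["kv"]),
        C0=float(merged["C0"]),
        lam=float(merged["lam"]),
        beta=float(merged["k_m2"]) / float(merged["k2"]),
        D_diff=2.0 * float(merged["k0"]) * float(merged["r_cell"]),
        delta1=delta / (1.0 + delta),
        delta2=1.0 / (1.0 + delta),
    )


def default_params() -> ModelParams:
    """The baseline parameter set."""
    return derive_params({})


def _modified_vasculature(base: ModelParams) -> ModelParams:
    # Narrow, leaky, slow vessel: kv -> 10 kv, lam -> lam/10, l -> l/2.
    return base.replace(kv=10.0 * base.kv, lam=base.lam / 10.0, l=base.l / 2.0)


def _strong_binding(base: ModelParams) -> ModelParams:
    # Much stronger binding, weaker unbinding than baseline.
    return base.replace(k2=2.95e-2, k_m2=4.38e-7)


#: Named parameter presets.
PRESETS = {
    "baseline": lambda base: base,
    "modified_vasculature": _modified_vasculature,
    "strong_binding": _strong_binding,
}


def apply_preset(name: str, base: ModelParams | None = None) -> ModelParams:
    """Return the named preset applied to ``base`` (default baseline)."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; valid: {sorted(PRESETS)}")
    return PRESETS[name](base if base is not None else default_params())
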