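"""Right-hand sides for all variants of the drug-transport model.

State variables are concentrations in μM: C1 free extracellular drug, C2
free intracellular drug, C3 drug bound to intracellular sites (finite site
concentration C0). The saturable reversible binding term is
``k2·C2·(C0 − C3) − k_m2·C3`` throughout.

Cord tissue states are arrays of shape (n shells, m discs); the vessel is
a 1D advective chain of m compartments fed by the PK profile at inflow.
All functions are pure: state in, time-derivative out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CordGrid, SphereGrid
from .params import ModelParams

__all__ = [
    "WellMixedSystem",
    "wellmixed_rhs",
    "irreversible_steady_state",
    "cord_rhs",
    "clamped_cord_rhs",
    "sphere_rhs",
    "cord_pack",
    "cord_unpack",
]


@dataclass(frozen=True)
class WellMixedSystem:
    """Geometry of the zero-dimensional (well-mixed) binding model.

    ``V1``/``V2`` are the extracellular/intracellular volumes (m³) and
    ``a`` the membrane interface area between them (m²).
    """

    V1: float
    V2: float
    a: float


def wellmixed_rhs(t: float, c: np.ndarray, p: ModelParams, sys: WellMixedSystem) -> np.ndarray:
    """Closed three-pool binding model: transmembrane exchange plus
    saturable reversible binding. ``c = (C1, C2, C3)`` in μM."""
    C1, C2, C3 = c
    exch = sys.a * p.k1 * (C2 - C1)
    bind = p.k2 * C2 * (p.C0 - C3) - p.k_m2 * C3
    return np.array([exch / sys.V1, -exch / sys.V2 - bind, bind])


def irreversible_steady_state(C1_0: float, p: ModelParams) -> tuple[float, float, float]:
    """Steady state of the well-mixed model in the irreversible limit β → 0.

    With no unbinding the drug binds until either the free drug is used up
    (dilute case, δ·C1(0) < C0) or the binding sites saturate. δ = V1/V2 is
    the extracellular:intracellular volume ratio.
    """
    if C1_0 < 0:
        raise ValueError("initial concentration must be >= 0")
    delta = p.delta
    if delta * C1_0 >= p.C0:
        free = (delta * C1_0 - p.C0) / (delta + 1.0)
        return (free, free, p.C0)
    return (0.0, 0.0, delta * C1_0)


# ---------------------------------------------------------------------------
# 2D cylindrical cord


def cord_pack(C1: np.ndarray, C2: np.ndarray, C3: np.ndarray, Cv: np.ndarray | None = None) -> np.ndarray:
    """Flatten tissue fields (n, m) [+ vessel (m,)] into a state vector."""
    parts = [np.ravel(C1), np.ravel(C2), np.ravel(C3)]
    if Cv is not None:
        parts.append(np.ravel(Cv))
    return np.concatenate(parts)

def cord_unpack(y: np.ndarray, g: CordGrid, vessel: bool = True):
    """Inverse of :func:`cord_pack`; returns (C1, C2, C3[, Cv]) views."""
    n, m = g.n, g.m
    N = n * m
    expected = 3 * N + (m if vessel else 0)
    if y.shape[-1] != expected:
        raise ValueError(f"state length {y.shape[-1]} != expected {expected}")
    C1 = y[..., :N].reshape(*y.shape[:-1], n, m)
    C2 = y[..., N : 2 * N].reshape(*y.shape[:-1], n, m)
    C3 = y[..., 2 * N : 3 * N].reshape(*y.shape[:-1], n, m)
    if vessel:
        return C1, C2, C3, y[..., 3 * N :]
    return C1, C2, C3


def _tissue_rhs(C1, C2, C3, Cv_row, g: CordGrid, p: ModelParams):
    """Tissue derivatives given the adjacent vessel concentrations Cv_row (m,)."""
    flux = np.zeros_like(C1)
    # interior radial diffusion across interfaces Ar[1..n-1]
    radial = p.k0 * g.Ar[1:-1, None] * (C1[1:, :] - C1[:-1, :])
    flux[:-1, :] += radial
    flux[1:, :] -= radial
    # vessel wall: permeability kv through the innermost interface
    flux[0, :] += g.Ar[0] * p.kv * (Cv_row - C1[0, :])
    # outer rim (Ar[n]) and both axial ends: no flux
    axial = p.k0 * g.Az[:, None] * (C1[:, 1:] - C1[:, :-1])
    flux[:, :-1] += axial
    flux[:, 1:] -= axial
    memb = g.a_mem[:, None] * p.k1 * (C2 - C1)
    bind = p.k2 * C2 * (p.C0 - C3) - p.k_m2 * C3
    dC1 = (flux + memb) / (p.delta1 * g.V[:, None])
    dC2 = -memb / (p.delta2 * g.V[:, None]) - bind
    dC3 = bind
    return dC1, dC2, dC3


def cord_rhs(t: float, y: np.ndarray, g: CordGrid, p: ModelParams, pk) -> np.ndarray:
    """Full 2D cord: tissue diffusion/exchange/binding plus vessel advection.

    The vessel is an upwinded advective chain with ghost inflow
    ``Cv_0 = pk(t)``; drug crosses the wall with permeability kv. No
    boundary condition is needed at the outflow end.
    """
    C1, C2, C3, Cv = cord_unpack(y, g)
    dC1, dC2, dC3 = _tissue_rhs(C1, C2, C3, Cv, g, p)
    Cv_prev = np.empty_like(Cv)
    Cv_prev[0] = pk(t)
    Cv_prev[1:] = Cv[:-1]
    dCv = (-g.Av * p.lam * (Cv - Cv_prev) + g.Ar[0] * p.kv * (C1[0, :] - Cv)) / g.Vv
    return cord_pack(dC1, dC2, dC3, dCv)


def clamped_cord_rhs(t: float, y: np.ndarray, g: CordGrid, p: ModelParams, pk) -> np.ndarray:
    """Cord tissue with the whole vessel clamped at the source profile.

    ``Cv_j := pk(t)`` for every disc, so an axially uniform state stays
    axially uniform and the dynamics reduce to a radial chain.
    """
    C1, C2, C3 = cord_unpack(y, g, vessel=False)
    cv = float(pk(t))
    dC1, dC2, dC3 = _tissue_rhs(C1, C2, C3, np.full(g.m, cv), g, p)
    return cord_pack(dC1, dC2, dC3)


# ---------------------------------------------------------------------------
# Avascular spheroid


def sphere_rhs(t: float, y: np.ndarray, g: SphereGrid, p: ModelParams, pk) -> np.ndarray:
    """Spherically symmetric shells bathed in well-vascularized tissue.

    Same three-pool physics per shell; zero flux at the centre (symmetry);
    the outermost shell exchanges with the external drug concentration
    pk(t) through the spheroid surface with intercellular permeability k0.
    """
    n = g.n
    if y.shape[-1] != 3 * n:
        raise ValueError(f"state length {y.shape[-1]} != expected {3 * n}")
    C1 = y[:n]
    C2 = y[n : 2 * n]
    C3 = y[2 * n :]
    flux = np.zeros(n)
    radial = p.k0 * g.A[1:-1] * (C1[1:] - C1[:-1])
    flux[:-1] += radial
    flux[1:] -= radial
    flux[-1] += p.k0 * g.A[-1] * (float(pk(t)) - C1[-1])
    a_mem = p.alpha * g.V
    memb = a_mem * p.k1 * (C2 - C1)
    bind = p.k2 * C2 * (p.C0 - C3) - p.k_m2 * C3
    dC1 = (flux + memb) / (p.delta1 * g.V)
    dC2 = -memb / (p.delta2 * g.V) - bind
    dC3 = bind
    return np.concatenate([dC1, dC2, dC3])
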