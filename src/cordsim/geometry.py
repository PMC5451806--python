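"""Compartment geometry: cylindrical cord shells/discs and spherical shells.

Shells are indexed 1..n in formulas but stored 0-based; interface areas sit
on half-indices i+1/2 and are stored in an (n+1)-length array, so the wall
(i = 1/2) is ``Ar[0]`` and the outer rim (i = n+1/2) is ``Ar[n]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams, ParameterError

__all__ = ["CordGrid", "SphereGrid", "build_cord_grid", "build_sphere_grid"]


@dataclass(frozen=True)
class CordGrid:
    """Cylindrical cord compartments around a single axial vessel.

    Per-disc shell volumes ``V[i] = π((2i+1)d + 2l)·d²`` (0-based i) are
    independent of the axial index; radial interface areas
    ``Ar[i] = 2π(l + i·d)·d`` increase outward; axial face areas ``Az``
    match the shell annulus cross-section. ``a_mem = alpha·V`` is the
    cellular membrane area inside one compartment. The vessel is divided
    into m discs of volume ``Vv = π l² d`` with cross-section ``Av = π l²``.
    """

    n: int
    m: int
    d: float
    l: float
    V: np.ndarray
    Ar: np.ndarray
    Az: np.ndarray
    a_mem: np.ndarray
    Vv: float
    Av: float

    @property
    def r_centres(self) -> np.ndarray:
        """Radial compartment centres measured from the cord axis, m."""
        return self.l + (np.arange(self.n) + 0.5) * self.d

    @property
    def z_centres(self) -> np.ndarray:
        """Axial compartment centres, m."""
        return (np.arange(self.m) + 0.5) * self.d


@dataclass(frozen=True)
class SphereGrid:
    """Concentric spherical shells for the avascular-spheroid variant.

    ``V[i] = (4/3)π(((i+1)d)³ − (i·d)³)``; interface areas ``A[i] = 4π(i·d)²``
    on half-indices (``A[0] = 0`` at the centre, ``A[n]`` the outer surface).
    """

    n: int
    d: float
    R: float
    V: np.ndarray
    A: np.ndarray


def build_cord_grid(p: ModelParams) -> CordGrid:
    """Compartment volumes and interface areas for the cord of ``p``."""
    n, m, d, l = p.n, p.m_discs, p.d, p.l
    i = np.arange(n)
    V = np.pi * ((2 * i + 1) * d + 2 * l) * d * d
    Ar = 2 * np.pi * (l + np.arange(n + 1) * d) * d
    Az = np.pi * ((2 * i + 1) * d + 2 * l) * d
    return CordGrid(
        n=n,
        m=m,
        d=d,
        l=l,
        V=V,
        Ar=Ar,
        Az=Az,
        a_mem=p.alpha * V,
        Vv=np.pi * l * l * d,
        Av=np.pi * l * l,
    )


def build_sphere_grid(R: float, d: float) -> SphereGrid:
    """Spherical shell grid of radius ``R`` with shell thickness ``d``.

    The shell count is round(R/d); R must be an integer multiple of d (to
    within rounding noise) so the shells tile the sphere exactly.
    """
    if not d > 0:
        raise ParameterError("shell thickness d must be > 0")
    if R < d:
        raise ParameterError(f"spheroid radius R={R!r} must be >= shell thickness d={d!r}")
    n = int(round(R / d))
    if abs(n * d - R) > 1e-9 * R:
        raise ParameterError(f"R={R!r} is not an integer multiple of d={d!r}")
    edges = np.arange(n + 1) * d
    V = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    A = 4.0 * np.pi * edges**2
    return SphereGrid(n=n, d=d, R=n * d, V=V, A=A)
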