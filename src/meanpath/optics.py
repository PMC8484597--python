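"""Interface optics: Snell refraction, unpolarized Fresnel reflectance,
total internal reflection and specular reflection.

Conventions used throughout the transport engine:

* the interface normal is oriented from the photon's current region
  toward the neighbouring region, so ``direction . normal > 0`` at an
  interface hit;
* light is scalar (unpolarized): the reflectance is the mean of the
  s- and p-polarized Fresnel coefficients;
* reflection vs transmission is resolved stochastically per photon,
  never by weight splitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit

__all__ = [
    "InterfaceEvent",
    "fresnel_reflectance",
    "refract",
    "reflect",
]


@dataclass(frozen=True)
class InterfaceEvent:
    """Outcome of one photon-interface interaction."""

    cos_incidence: float
    n_from: float
    n_to: float
    outcome: str  # "transmit" | "reflect"
    new_direction: np.ndarray


@njit(cache=True, inline="always")
def _fresnel(cos_i, n_from, n_to):
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n_from / n_to) ** 2 * sin_i2
    if sin_t2 >= 1.0:  # total internal reflection
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_from * cos_i - n_to * cos_t) / (n_from * cos_i + n_to * cos_t)
    rp = (n_to * cos_i - n_from * cos_t) / (n_to * cos_i + n_from * cos_t)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always")
def _refract(ux, uy, uz, nx, ny, nz, n_from, n_to):
    """Snell-refracted direction; returns (ok, x, y, z); ok=False on TIR."""
    cos_i = ux * nx + uy * ny + uz * nz
    eta = n_from / n_to
    sin_t2 = eta * eta * (1.0 - cos_i * cos_i)
    if sin_t2 > 1.0:
        return False, 0.0, 0.0, 0.0
    cos_t = np.sqrt(1.0 - sin_t2)
    a = cos_t - eta * cos_i
    tx = eta * ux + a * nx
    ty = eta * uy + a * ny
    tz = eta * uz + a * nz
    inv = 1.0 / np.sqrt(tx * tx + ty * ty + tz * tz)
    return True, tx * inv, ty * inv, tz * inv


@njit(cache=True, inline="always")
def _reflect(ux, uy, uz, nx, ny, nz):
    d = 2.0 * (ux * nx + uy * ny + uz * nz)
    return ux - d * nx, uy - d * ny, uz - d * nz


def fresnel_reflectance(cos_incidence: float, n_from: float, n_to: float) -> float:
    """Unpolarized Fresnel power reflectance R in [0, 1].

    R = (R_s + R_p) / 2; R = 1 under total internal reflection.
    Satisfies reciprocity: 1 - R is the same evaluated from either side
    at Snell-conjugate angles.
    """
    if not (0.0 < cos_incidence <= 1.0):
        raise ValueError("cos_incidence must lie in (0, 1]")
    if n_from <= 0.0 or n_to <= 0.0:
        raise ValueError("refractive indices must be positive")
    return float(_fresnel(cos_incidence, n_from, n_to))


def refract(
    direction: np.ndarray, normal: np.ndarray, n_from: float, n_to: float
) -> Optional[np.ndarray]:
    """Snell-refracted unit direction, or None on total internal reflection.

    ``normal`` must be oriented toward the target region
    (``direction . normal > 0``).
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    if d @ n <= 0.0:
        raise ValueError("normal must point toward the target region")
    ok, x, y, z = _refract(d[0], d[1], d[2], n[0], n[1], n[2], n_from, n_to)
    if not ok:
        return None
    return np.array([x, y, z])


def reflect(direction: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Specular reflection d' = d - 2 (d.n) n."""
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    x, y, z = _reflect(d[0], d[1], d[2], n[0], n[1], n[2])
    return np.array([x, y, z])


def interface_event(
    direction: np.ndarray,
    normal: np.ndarray,
    n_from: float,
    n_to: float,
    xi: float,
) -> InterfaceEvent:
    """Resolve one interface interaction stochastically.

    The photon transmits when the deviate ``xi`` exceeds the Fresnel
    reflectance (which is 1 under TIR, so TIR always reflects).
    """
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    cos_i = float(d @ n)
    r = fresnel_reflectance(cos_i, n_from, n_to)
    if xi < r:
        return InterfaceEvent(cos_i, n_from, n_to, "reflect", reflect(d, n))
    out = refract(d, n, n_from, n_to)
    assert out is not None  # xi >= R = 1 impossible under TIR
    return InterfaceEvent(cos_i, n_from, n_to, "transmit", out)
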