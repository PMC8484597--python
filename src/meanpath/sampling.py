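"""Stochastic primitives of the transport engine.

All samplers are inverse-CDF transforms of a single uniform deviate:

* free path between scattering events, exponential with rate mu_s
  (``l = -ln(1 - xi) / mu_s``);
* Henyey-Greenstein deflection cosine with anisotropy g
  (closed-form invertible CDF; g = 0 reduces to an isotropic cosine);
* Lambertian entrance polar angle ``theta = arccos(sqrt(1 - xi))``
  (density 2 sin(theta) cos(theta), i.e. constant incoming radiance);
* uniform azimuth ``phi = 2 pi xi``.

The scalar njit versions are shared verbatim with the compiled photon
kernel so that Python-level tests exercise the exact code the ensemble
runner executes.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._rng import RandomStream  # re-exported: the stream lives with its samplers

__all__ = [
    "RandomStream",
    "INFINITE_PATH",
    "sample_free_path",
    "sample_hg_cosine",
    "sample_lambertian_polar",
    "sample_azimuth",
    "rotate_direction",
]

#: Sentinel returned for mu_s = 0: the photon flies to the next interface.
INFINITE_PATH = np.inf


@njit(cache=True, inline="always")
def _free_path(xi, mu_s):
    if mu_s == 0.0:
        return np.inf
    return -np.log1p(-xi) / mu_s


@njit(cache=True, inline="always")
def _hg_cosine(xi, g):
    if g == 0.0:
        return 2.0 * xi - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    c = (1.0 + g * g - f * f) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, inline="always")
def _lambertian_polar(xi):
    return np.arccos(np.sqrt(1.0 - xi))


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cos_s, phi):
    """Rotate a unit vector by polar angle arccos(cos_s) and azimuth phi
    about itself (standard local-frame scattering update)."""
    sin_s = np.sqrt(max(0.0, 1.0 - cos_s * cos_s))
    cos_p = np.cos(phi)
    sin_p = np.sin(phi)
    if abs(uz) > 1.0 - 1e-12:
        # old direction (anti)parallel to z: the local frame is trivial
        nx = sin_s * cos_p
        ny = sin_s * sin_p
        nz = cos_s if uz > 0.0 else -cos_s
        if uz < 0.0:
            ny = -ny
        return nx, ny, nz
    den = np.sqrt(1.0 - uz * uz)
    nx = sin_s * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_s
    ny = sin_s * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_s
    nz = -sin_s * cos_p * den + uz * cos_s
    inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx * inv, ny * inv, nz * inv


def sample_free_path(xi: float, mu_s: float) -> float:
    """Exponential free path -ln(1 - xi)/mu_s in mm.

    mu_s = 0 returns the infinite-path sentinel: the photon travels
    ballistically to the next interface.
    """
    if mu_s < 0.0:
        raise ValueError("mu_s must be non-negative")
    if not (0.0 <= xi < 1.0):
        raise ValueError("xi must lie in [0, 1)")
    return float(_free_path(xi, mu_s))


def sample_hg_cosine(xi: float, g: float) -> float:
    """Henyey-Greenstein deflection cosine via the closed-form inverse CDF."""
    if not (-1.0 < g < 1.0):
        raise ValueError("anisotropy g must lie in (-1, 1)")
    return float(_hg_cosine(xi, g))


def sample_lambertian_polar(xi: float) -> float:
    """Lambertian entrance polar angle arccos(sqrt(1 - xi)) in [0, pi/2)."""
    return float(_lambertian_polar(xi))


def sample_azimuth(xi: float) -> float:
    """Uniform azimuth 2 pi xi in [0, 2 pi)."""
    return 2.0 * math.pi * xi


def rotate_direction(direction: np.ndarray, cos_s: float, phi: float) -> np.ndarray:
    """New unit direction at deflection cosine ``cos_s`` and azimuth ``phi``
    relative to ``direction``; dot(new, old) == cos_s."""
    d = np.asarray(direction, dtype=float)
    x, y, z = _rotate(d[0], d[1], d[2], cos_s, phi)
    return np.array([x, y, z])
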