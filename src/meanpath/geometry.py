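"""Layered media: concentric spheres and laterally-infinite layered slabs.

Layers are indexed 1-based in user-facing structures, outermost-first
for the sphere and entry-face-first (z = 0 side) for the slab, matching
how layered tissue phantoms are usually tabulated.  The slab is
laterally unbounded: x and y never enter the intersection logic, and
its V/S uses the per-unit-area convention V/S = d/2 (the illuminated
area appears on both faces), which makes the invariance reference for a
matched slab of thickness d equal to 2d.

Coordinates are in mm and scattering coefficients in mm^-1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from numba import njit

__all__ = [
    "LayerSpec",
    "LayeredMedium",
    "layer_volume_ratio",
    "distance_to_interface",
    "interface_normal",
]

#: distances below this are treated as "photon sits on that interface"
INTERSECT_TOL = 1e-12


@dataclass(frozen=True)
class LayerSpec:
    """One homogeneous region of a layered medium.

    ``inner``/``outer`` are radii for a sphere (outer > inner >= 0) and
    the depth interval [inner, outer) for a slab.
    """

    index: int
    inner: float
    outer: float
    n: float
    mu_s: float
    g: float = 0.0

    def __post_init__(self):
        if self.outer <= self.inner:
            raise ValueError(f"layer {self.index}: outer bound must exceed inner bound")
        if self.mu_s < 0.0:
            raise ValueError(f"layer {self.index}: mu_s must be >= 0")
        if self.n <= 0.0:
            raise ValueError(f"layer {self.index}: refractive index must be > 0")
        if not (-1.0 < self.g < 1.0):
            raise ValueError(f"layer {self.index}: anisotropy g must lie in (-1, 1)")

    @property
    def thickness(self) -> float:
        return self.outer - self.inner


@dataclass(frozen=True)
class LayeredMedium:
    """A layered sphere or laterally-infinite layered slab.

    ``layers`` must tile the domain contiguously: down to radius 0 for
    the sphere (ordered outermost-first) and over [0, d] for the slab
    (ordered entry-face-first).
    """

    kind: str  # "sphere" | "slab"
    n_external: float
    layers: Tuple[LayerSpec, ...]
    outer_dimension: float = field(init=False)

    def __post_init__(self):
        if self.kind not in ("sphere", "slab"):
            raise ValueError("kind must be 'sphere' or 'slab'")
        if self.n_external <= 0.0:
            raise ValueError("external refractive index must be > 0")
        if not self.layers:
            raise ValueError("at least one layer is required")
        object.__setattr__(self, "layers", tuple(self.layers))
        ls = self.layers
        if self.kind == "sphere":
            if ls[-1].inner != 0.0:
                raise ValueError("sphere layers must reach radius 0")
            for a, b in zip(ls, ls[1:]):
                if a.inner != b.outer:
                    raise ValueError(
                        f"layers {a.index} and {b.index} do not tile contiguously"
                    )
            object.__setattr__(self, "outer_dimension", ls[0].outer)
        else:
            if ls[0].inner != 0.0:
                raise ValueError("slab layers must start at depth 0")
            for a, b in zip(ls, ls[1:]):
                if a.outer != b.inner:
                    raise ValueError(
                        f"layers {a.index} and {b.index} do not tile contiguously"
                    )
            object.__setattr__(self, "outer_dimension", ls[-1].outer)

    # -- derived quantities -------------------------------------------------

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def volume_surface_ratio(self) -> float:
        """V/S of the whole body: r/3 for a sphere, d/2 for a slab."""
        if self.kind == "sphere":
            return self.outer_dimension / 3.0
        return self.outer_dimension / 2.0

    # -- kernel export ------------------------------------------------------

    def as_arrays(self):
        """(kind_code, edges, n_k, mu_s_k, g_k) in kernel layout.

        Sphere: ``edges`` are the K+1 interface radii, decreasing from r
        to 0, region k lying between edges[k] and edges[k+1].  Slab:
        K+1 depths increasing from 0 to d, region k in
        [edges[k], edges[k+1]].
        """
        k = self.n_layers
        edges = np.empty(k + 1, dtype=np.float64)
        n_k = np.empty(k, dtype=np.float64)
        mu = np.empty(k, dtype=np.float64)
        g = np.empty(k, dtype=np.float64)
        for i, layer in enumerate(self.layers):
            n_k[i] = layer.n
            mu[i] = layer.mu_s
            g[i] = layer.g
            if self.kind == "sphere":
                edges[i] = layer.outer
            else:
                edges[i] = layer.inner
        edges[k] = 0.0 if self.kind == "sphere" else self.outer_dimension
        kind_code = 0 if self.kind == "sphere" else 1
        return kind_code, edges, n_k, mu, g


def layer_volume_ratio(medium: LayeredMedium, k: int) -> float:
    """Geometric factor V_k/S of layer k (1-based) in mm.

    Sphere shell (a, b) inside radius r: (b^3 - a^3) / (3 r^2);
    slab layer of thickness t: t/2 (per-unit-area, two illuminated
    faces).  The values sum to V/S of the whole body.
    """
    if not (1 <= k <= medium.n_layers):
        raise IndexError(f"layer index {k} out of range 1..{medium.n_layers}")
    layer = medium.layers[k - 1]
    if medium.kind == "sphere":
        r = medium.outer_dimension
        return (layer.outer**3 - layer.inner**3) / (3.0 * r * r)
    return layer.thickness / 2.0


# -- ray/interface intersection (shared with the compiled kernel) ----------


@njit(cache=True, inline="always")
def _sphere_distance(px, py, pz, ux, uy, uz, r_out, r_in):
    """Distance to the boundary of the shell (r_in, r_out) and crossing
    sense: returns (t, outward) with outward=True for the r_out sphere.

    The quadratic is solved in the q-formulation to stay accurate near
    tangency.
    """
    b = px * ux + py * uy + pz * uz
    rho2 = px * px + py * py + pz * pz
    # inner sphere first: only reachable heading inward (b < 0)
    if r_in > 0.0 and b < 0.0:
        c_in = rho2 - r_in * r_in
        disc = b * b - c_in
        if disc > 0.0 and c_in > 0.0:
            t_in = c_in / (-b + np.sqrt(disc))
            if t_in > INTERSECT_TOL:
                return t_in, False
    c_out = rho2 - r_out * r_out
    disc = b * b - c_out
    # from inside (c_out <= 0) the outward root is -b + sqrt(disc) >= 0
    t_out = -b + np.sqrt(max(disc, 0.0))
    return t_out, True


@njit(cache=True, inline="always")
def _slab_distance(z, uz, z_lo, z_hi):
    """Distance to the bounding plane of [z_lo, z_hi] along uz; returns
    (t, outward) with outward=True for the z_hi plane.  uz = 0 never
    reaches a plane (t = inf)."""
    if uz > 0.0:
        return (z_hi - z) / uz, True
    if uz < 0.0:
        return (z_lo - z) / uz, False
    return np.inf, True


def distance_to_interface(
    position: np.ndarray,
    direction: np.ndarray,
    region: int,
    medium: LayeredMedium,
):
    """Distance from ``position`` along ``direction`` to the boundary of
    layer ``region`` (1-based).

    Returns ``(distance_mm, interface_id, outward)`` where
    ``interface_id`` numbers the bounding surfaces from the outside in
    (0 is the external surface; i is the interface between layers i and
    i+1) for the sphere, and from the entry face in depth order for the
    slab; ``outward`` is True when the photon is heading toward the
    lower-index neighbour (sphere) / larger-depth side (slab).
    """
    p = np.asarray(position, dtype=float)
    u = np.asarray(direction, dtype=float)
    if abs(u @ u - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    if not (1 <= region <= medium.n_layers):
        raise IndexError("invalid region index")
    layer = medium.layers[region - 1]
    if medium.kind == "sphere":
        t, outward = _sphere_distance(p[0], p[1], p[2], u[0], u[1], u[2], layer.outer, layer.inner)
        interface_id = region - 1 if outward else region
    else:
        t, outward = _slab_distance(p[2], u[2], layer.inner, layer.outer)
        interface_id = region if outward else region - 1
    if not np.isfinite(t) or t <= 0.0:
        raise RuntimeError("no forward interface intersection: geometry corrupted")
    return float(t), int(interface_id), bool(outward)


def interface_normal(
    medium: LayeredMedium, interface_id: int, point: np.ndarray, outward: bool
) -> np.ndarray:
    """Unit normal at ``point`` on the given interface, oriented from the
    photon's current region toward the neighbour it is heading into."""
    p = np.asarray(point, dtype=float)
    if medium.kind == "sphere":
        rho = np.linalg.norm(p)
        if rho == 0.0:
            raise ValueError("sphere normal undefined at the origin")
        n = p / rho
        return n if outward else -n
    return np.array([0.0, 0.0, 1.0]) if outward else np.array([0.0, 0.0, -1.0])
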