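"""Closed-form invariance-property (IP) references.

For Lambertian (constant-radiance) illumination of a non-absorbing
medium the mean path length of the received random walkers is a purely
geometric invariant -- Cauchy's mean-chord formula, generalized to
refractive-index mismatches:

    <L>_IP = 4 (V/S) n_r^2          (3D)
    <L>_IP = pi (S/P) n_r           (2D)

independently of the scattering coefficient and phase function.  For a
medium partitioned into sub-volumes V_k of index n_k the invariant
splits additively over the parts:

    <L_k>_IP = 4 (n_k / n_e)^2 V_k / S,      <L>_IP = sum_k <L_k>_IP.

The only validity restriction: for non-ergodic shapes (sphere, slab) a
region with n_k > n_e must have mu_s > 0, otherwise guided (trapped)
ballistic trajectories break the equilibrium argument and <L_k> is
discontinuous at mu_s = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .geometry import LayeredMedium, layer_volume_ratio

__all__ = [
    "IPReference",
    "ip_mean_path_3d",
    "ip_mean_path_2d",
    "ip_partial_paths",
    "ip_validity_check",
]


@dataclass(frozen=True)
class IPReference:
    """IP reference values for a layered medium (all in mm)."""

    total: float
    per_layer: Tuple[float, ...]
    valid: bool
    warnings: Tuple[str, ...] = ()


def ip_mean_path_3d(volume: float, surface: float, n_r: float = 1.0) -> float:
    """Cauchy mean chord 4 (V/S) n_r^2 in mm.

    Deliberately takes no scattering arguments: the reference is
    invariant under any mu_s or phase function.
    """
    if volume <= 0.0 or surface <= 0.0:
        raise ValueError("volume and surface must be positive")
    return 4.0 * (volume / surface) * n_r * n_r


def ip_mean_path_2d(area: float, perimeter: float, n_r: float = 1.0) -> float:
    """2D analogue pi (S/P) n_r in mm (reference value only; the
    transport engine is 3D)."""
    if area <= 0.0 or perimeter <= 0.0:
        raise ValueError("area and perimeter must be positive")
    return math.pi * (area / perimeter) * n_r


def ip_partial_paths(medium: LayeredMedium) -> IPReference:
    """Per-layer references 4 (n_k/n_e)^2 V_k/S and their sum."""
    per_layer = []
    for k in range(1, medium.n_layers + 1):
        layer = medium.layers[k - 1]
        n_r = layer.n / medium.n_external
        per_layer.append(4.0 * n_r * n_r * layer_volume_ratio(medium, k))
    valid, warnings = ip_validity_check(medium)
    return IPReference(
        total=float(sum(per_layer)),
        per_layer=tuple(per_layer),
        valid=valid,
        warnings=tuple(warnings),
    )


def ip_validity_check(medium: LayeredMedium) -> Tuple[bool, List[str]]:
    """IP validity for non-ergodic bodies: flags layers with
    n_k > n_e and mu_s = 0 (guided ballistic trajectories)."""
    warnings = []
    for layer in medium.layers:
        if layer.n > medium.n_external and layer.mu_s == 0.0:
            warnings.append(
                f"layer {layer.index}: n={layer.n} > n_e={medium.n_external} with "
                "mu_s=0 supports guided ballistic trajectories; the invariance "
                "reference does not apply to this configuration"
            )
    return (len(warnings) == 0), warnings
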