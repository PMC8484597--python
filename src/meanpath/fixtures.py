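"""Reference media used throughout the verification studies.

* ``sphere_homog_r5``  -- homogeneous sphere, r = 5 mm (default
  mu_s = 0.1 mm^-1, g = 0, matched index).
* ``slab_d10``         -- homogeneous laterally-infinite slab, d = 10 mm.
* ``table2_sphere``    -- 4-layer sphere, r = 5 mm, interfaces at 4, 3,
  2 mm; n = (1.75, 1.5, 1.25, 1) outermost-first in external index 2;
  mu_s = (mu_s0, 0, mu_s0, 0).
* ``caseI_sphere_100`` -- 100-layer sphere, r = 5 mm, core radius
  0.5 mm with 99 equal shells above it; n_k = 2 - 0.01 k, n_e = 2.
* ``caseII_slab_100``  -- 100 x 0.1 mm slab layers, n_k = 2 - 0.01 k
  (monotone profile), n_e = 2.
* ``caseIII_slab_100`` -- mirrored profile, n_k = 2 - 0.02 k for
  k <= 50 and 2 - 0.02 (101 - k) for k > 50, so n_1 = n_100 = 1.98 and
  n_50 = n_51 = 1.00.

The 100-layer media default to mu_s = 0, which keeps the invariance
reference valid since every n_k < n_e.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .geometry import LayerSpec, LayeredMedium

__all__ = ["FIXTURE_NAMES", "build_fixture"]

FIXTURE_NAMES = (
    "sphere_homog_r5",
    "slab_d10",
    "table2_sphere",
    "caseI_sphere_100",
    "caseII_slab_100",
    "caseIII_slab_100",
)


def _sphere_from_shells(radii_desc, n_values, mu_values, g, n_e):
    layers = []
    for i in range(len(radii_desc) - 1):
        layers.append(
            LayerSpec(
                index=i + 1,
                inner=radii_desc[i + 1],
                outer=radii_desc[i],
                n=n_values[i],
                mu_s=mu_values[i],
                g=g,
            )
        )
    return LayeredMedium(kind="sphere", n_external=n_e, layers=tuple(layers))


def _slab_from_edges(edges, n_values, mu_values, g, n_e):
    layers = [
        LayerSpec(index=i + 1, inner=edges[i], outer=edges[i + 1], n=n_values[i], mu_s=mu_values[i], g=g)
        for i in range(len(edges) - 1)
    ]
    return LayeredMedium(kind="slab", n_external=n_e, layers=tuple(layers))


def build_fixture(
    name: str,
    mu_s: float = None,
    mu_s0: float = 1.0,
    g: float = 0.0,
    n_r: float = 1.0,
) -> LayeredMedium:
    """Build one of the named reference media.

    ``mu_s`` sets the (uniform) scattering coefficient where it is a
    free parameter; ``mu_s0`` is the alternating coefficient of the
    4-layer sphere; ``n_r`` scales the homogeneous media's relative
    index (n_e stays 1).
    """
    if name == "sphere_homog_r5":
        ms = 0.1 if mu_s is None else mu_s
        return _sphere_from_shells([5.0, 0.0], [n_r], [ms], g, 1.0)

    if name == "slab_d10":
        ms = 0.0 if mu_s is None else mu_s
        return _slab_from_edges([0.0, 10.0], [n_r], [ms], g, 1.0)

    if name == "table2_sphere":
        return _sphere_from_shells(
            [5.0, 4.0, 3.0, 2.0, 0.0],
            [1.75, 1.5, 1.25, 1.0],
            [mu_s0, 0.0, mu_s0, 0.0],
            g,
            2.0,
        )

    ms = 0.0 if mu_s is None else mu_s

    if name == "caseI_sphere_100":
        # core radius 0.5 mm, 99 equal shells over (0.5, 5] mm
        radii = np.concatenate([np.linspace(5.0, 0.5, 100), [0.0]])
        n_values = [2.0 - 0.01 * k for k in range(1, 101)]
        return _sphere_from_shells(radii, n_values, [ms] * 100, g, 2.0)

    if name == "caseII_slab_100":
        edges = np.linspace(0.0, 10.0, 101)
        n_values = [2.0 - 0.01 * k for k in range(1, 101)]
        return _slab_from_edges(edges, n_values, [ms] * 100, g, 2.0)

    if name == "caseIII_slab_100":
        edges = np.linspace(0.0, 10.0, 101)
        n_values = [
            2.0 - 0.02 * k if k <= 50 else 2.0 - 0.02 * (101 - k)
            for k in range(1, 101)
        ]
        return _slab_from_edges(edges, n_values, [ms] * 100, g, 2.0)

    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
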