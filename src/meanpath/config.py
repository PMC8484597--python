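"""Run configuration: YAML/TOML parsing and validation.

Schema (YAML shown; TOML is equivalent)::

    medium:
      kind: sphere            # or slab
      outer_radius_mm: 5.0    # thickness_mm for a slab
      n_external: 1.0
      layers:                 # outermost-first (sphere) / entry-face-first (slab)
        - {bounds_mm: [4.0, 5.0], n: 1.75, mus_per_mm: 1.0, g: 0.0}
        ...
    run:
      photons: 1000000
      seed: 1
      rng_quantization_eps: 0.0     # 0 disables; see precision module
      max_boundary_events: 0        # 0 = unlimited
      histogram: {enabled: false, bin_width_mm: 0.1, max_mm: 50.0}
    test:
      alpha: 0.05
      tails: two
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .geometry import LayerSpec, LayeredMedium
from .invariance import ip_validity_check

__all__ = ["RunConfig", "HistogramSpec", "load_config", "medium_from_dict", "medium_to_dict"]

log = logging.getLogger("meanpath")


@dataclass(frozen=True)
class HistogramSpec:
    enabled: bool = False
    bin_width_mm: float = 0.1
    max_mm: float = 50.0

    @property
    def n_bins(self) -> int:
        return int(round(self.max_mm / self.bin_width_mm))


@dataclass(frozen=True)
class RunConfig:
    """Fully validated simulation + verification configuration."""

    medium: LayeredMedium
    photons: int
    seed: int
    rng_quantization_eps: float = 0.0
    max_boundary_events: int = 0
    histogram: HistogramSpec = field(default_factory=HistogramSpec)
    alpha: float = 0.05
    tails: str = "two"

    def __post_init__(self):
        errors = []
        if self.photons < 1:
            errors.append("run.photons must be >= 1")
        if not (0.0 <= self.rng_quantization_eps < 1.0):
            errors.append("run.rng_quantization_eps must lie in [0, 1)")
        if self.max_boundary_events < 0:
            errors.append("run.max_boundary_events must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            errors.append("test.alpha must lie in (0, 1)")
        if self.tails not in ("two", "less", "greater"):
            errors.append("test.tails must be 'two', 'less' or 'greater'")
        if errors:
            raise ValueError("; ".join(errors))


def medium_from_dict(spec: dict) -> LayeredMedium:
    """Build a LayeredMedium from the ``medium`` config section."""
    errors = []
    kind = spec.get("kind")
    if kind not in ("sphere", "slab"):
        errors.append("medium.kind must be 'sphere' or 'slab'")
    dim_key = "outer_radius_mm" if kind == "sphere" else "thickness_mm"
    outer = spec.get(dim_key)
    if outer is None or outer <= 0:
        errors.append(f"medium.{dim_key} must be a positive number")
    n_e = spec.get("n_external", 1.0)
    raw_layers = spec.get("layers")
    if not raw_layers:
        errors.append("medium.layers must be a non-empty list")
    if errors:
        raise ValueError("; ".join(errors))

    layers = []
    for i, entry in enumerate(raw_layers, start=1):
        try:
            lo, hi = entry["bounds_mm"]
            if kind == "sphere":
                # user gives [inner_radius, outer_radius]
                inner, outer_b = float(min(lo, hi)), float(max(lo, hi))
            else:
                inner, outer_b = float(min(lo, hi)), float(max(lo, hi))
            layers.append(
                LayerSpec(
                    index=i,
                    inner=inner,
                    outer=outer_b,
                    n=float(entry["n"]),
                    mu_s=float(entry.get("mus_per_mm", 0.0)),
                    g=float(entry.get("g", 0.0)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"medium.layers[{i}]: {exc}")
    if errors:
        raise ValueError("; ".join(errors))
    if kind == "sphere":
        layers.sort(key=lambda l: -l.outer)
    else:
        layers.sort(key=lambda l: l.inner)
    layers = [
        LayerSpec(index=i, inner=l.inner, outer=l.outer, n=l.n, mu_s=l.mu_s, g=l.g)
        for i, l in enumerate(layers, start=1)
    ]
    medium = LayeredMedium(kind=kind, n_external=float(n_e), layers=tuple(layers))
    if abs(medium.outer_dimension - outer) > 1e-9:
        raise ValueError(
            f"medium.{dim_key}={outer} does not match the layer bounds "
            f"(outermost bound {medium.outer_dimension})"
        )
    return medium


def medium_to_dict(medium: LayeredMedium) -> dict:
    """Inverse of medium_from_dict, for emitting fixture configs."""
    dim_key = "outer_radius_mm" if medium.kind == "sphere" else "thickness_mm"
    return {
        "kind": medium.kind,
        dim_key: medium.outer_dimension,
        "n_external": medium.n_external,
        "layers": [
            {
                "bounds_mm": [layer.inner, layer.outer],
                "n": layer.n,
                "mus_per_mm": layer.mu_s,
                "g": layer.g,
            }
            for layer in medium.layers
        ],
    }


def load_config(path) -> RunConfig:
    """Parse and validate a YAML or TOML run configuration.

    A medium that violates IP validity (some n_k > n_e with mu_s = 0)
    loads fine but logs a warning: the discontinuity at mu_s = 0 is
    physics, not a crash condition.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".toml", ".tml"):
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "medium" not in raw:
        raise ValueError("config must contain a 'medium' section")
    medium = medium_from_dict(raw["medium"])
    run = raw.get("run", {})
    if "seed" not in run:
        raise ValueError("run.seed is required (no silent nondeterminism)")
    hist_raw = run.get("histogram", {})
    hist = HistogramSpec(
        enabled=bool(hist_raw.get("enabled", False)),
        bin_width_mm=float(hist_raw.get("bin_width_mm", 0.1)),
        max_mm=float(hist_raw.get("max_mm", 50.0)),
    )
    test = raw.get("test", {})
    cfg = RunConfig(
        medium=medium,
        photons=int(run.get("photons", 1_000_000)),
        seed=int(run["seed"]),
        rng_quantization_eps=float(run.get("rng_quantization_eps", 0.0)),
        max_boundary_events=int(run.get("max_boundary_events", 0)),
        histogram=hist,
        alpha=float(test.get("alpha", 0.05)),
        tails=str(test.get("tails", "two")),
    )
    valid, warnings = ip_validity_check(medium)
    for w in warnings:
        log.warning("IP validity: %s", w)
    return cfg
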