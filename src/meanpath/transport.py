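"""Photon life cycle and ensemble runner.

A photon is launched through the external surface with a Lambertian
(cosine-law) entrance angle, undergoes entry Fresnel reflection
stochastically, then alternates exponential free flights, HG scattering
and interface events until it exits through the external boundary.
Interface crossings redraw the free path with the local mu_s (the
memoryless exponential makes this exact).  There is no absorption:
every launched photon is eventually received, and absorption can be
applied afterwards by Beer-Lambert re-weighting of the recorded
per-region partial paths.

Ensemble convention: photons Fresnel-reflected at first incidence are
counted in the ensemble with L = 0.  Under external-Lambertian
illumination this all-incident average is the one that equals the
invariance reference 4 (V/S) n_r^2 exactly (Snell maps the external
cosine law onto the internal one with weight n_r^2, and Fresnel
reciprocity balances entry refusals against internal escape refusals).

Symmetry is exploited exactly as a practitioner would: the sphere is
illuminated at the single point (0, 0, r); the slab alternates its two
faces deterministically (even photon index -> z = 0 face) so each face
receives exactly half the photons, as asymmetric layer profiles
require.

Fault injection ("mutations") for verification-sensitivity studies:
``no_fresnel`` removes reflection at every boundary (photons always
transmit; where no refracted direction exists -- total internal
reflection -- they pass straight through unbent), ``biased_hg``
draws the scattering azimuth from [0, pi) instead of [0, 2 pi) (the
classic missing factor of two, which makes the scattering kernel
non-isotropy-preserving), ``truncated_lambertian`` caps the
entrance-angle deviate at 0.75 (theta_in <= 60 degrees).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from ._rng import init_state, next_uniform
from .geometry import LayeredMedium, _slab_distance, _sphere_distance
from .optics import _fresnel, _reflect, _refract
from .sampling import _free_path, _hg_cosine, _rotate

__all__ = [
    "PhotonState",
    "TrajectoryRecord",
    "EnsembleTallies",
    "launch_photon",
    "simulate_photon",
    "run_ensemble",
    "apply_absorption_weight",
    "MUTATIONS",
]

MUTATIONS = {"none": 0, "no_fresnel": 1, "biased_hg": 2, "truncated_lambertian": 3}

_TOL = 1e-12


@dataclass
class PhotonState:
    """Mutable in-flight photon: position (mm), unit direction, current
    layer (1-based) and the per-region paths accumulated so far."""

    position: np.ndarray
    direction: np.ndarray
    region: int
    partial_paths: np.ndarray
    entered: bool = True


@dataclass(frozen=True)
class TrajectoryRecord:
    """One finished photon: total path L (mm), per-region partial paths
    (mm), event counts, and whether it entered the medium at all."""

    total_path: float
    partial_paths: np.ndarray
    n_scatterings: int
    n_boundary_events: int
    entered: bool
    capped: bool = False


@dataclass
class EnsembleTallies:
    """Streaming moments of L and each partial path over an ensemble."""

    n: int
    sum_L: float
    sum_L2: float
    sum_lk: np.ndarray
    sum_lk2: np.ndarray
    n_entered: int
    n_capped: int
    n_scatterings: int
    histogram_counts: Optional[np.ndarray] = None
    histogram_bin_width: Optional[float] = None
    paths: Optional[np.ndarray] = None  # per-photon L, when recorded

    @property
    def mean_L(self) -> float:
        return self.sum_L / self.n


# --------------------------------------------------------------------------
# compiled single-photon trace
# --------------------------------------------------------------------------


@njit(cache=True)
def _draw(state, eps, quantize):
    xi = next_uniform(state)
    if quantize and eps > 0.0:
        xi = np.floor(xi / eps) * eps
    return xi


@njit(cache=True)
def _trace_one(
    kind,
    edges,
    n_k,
    mu_k,
    g_k,
    n_e,
    state,
    photon_index,
    eps,
    entrance_only,
    mutation,
    max_events,
    lk,
):
    """Simulate one photon; fills lk (per-region path, mm) in place.

    Returns (L, n_scatterings, n_boundary_events, entered, capped).
    """
    n_regions = n_k.shape[0]
    for i in range(n_regions):
        lk[i] = 0.0

    # ---- launch: Lambertian external angle + entry Fresnel ----
    xi_theta = _draw(state, eps, True)
    if mutation == 3 and xi_theta > 0.75:  # truncated Lambertian entrance
        xi_theta = 0.75
    cos_e = np.sqrt(1.0 - xi_theta)
    sin_e = np.sqrt(xi_theta)
    phi = 2.0 * np.pi * _draw(state, eps, not entrance_only)

    if kind == 0:  # sphere: entry point (0, 0, r), inward normal -z
        px, py, pz = 0.0, 0.0, edges[0]
        region = 0
        nx, ny, nz = 0.0, 0.0, -1.0
    else:  # slab: alternate faces by photon parity
        if photon_index % 2 == 0:
            px, py, pz = 0.0, 0.0, 0.0
            nx, ny, nz = 0.0, 0.0, 1.0
            region = 0
        else:
            px, py, pz = 0.0, 0.0, edges[n_regions]
            nx, ny, nz = 0.0, 0.0, -1.0
            region = n_regions - 1

    n_first = n_k[region]
    if mutation != 1:
        r_entry = _fresnel(cos_e, n_e, n_first)
        if _draw(state, eps, not entrance_only) < r_entry:
            return 0.0, 0, 0, False, False  # refused at surface, counted with L = 0

    # refract the external direction (polar cos_e about the inward normal)
    # build external direction in the local frame of the inward normal
    if kind == 0:
        ux = sin_e * np.cos(phi)
        uy = sin_e * np.sin(phi)
        uz = -cos_e
    else:
        ux = sin_e * np.cos(phi)
        uy = sin_e * np.sin(phi)
        uz = cos_e * nz
    ok, tx, ty, tz = _refract(ux, uy, uz, nx, ny, nz, n_e, n_first)
    if ok:
        ux, uy, uz = tx, ty, tz
    elif mutation != 1:  # total external reflection already folded into r_entry
        return 0.0, 0, 0, False, False

    # ---- free flight / scatter / interface loop ----
    total = 0.0
    n_scat = 0
    n_bound = 0
    capped = False
    while True:
        step = _free_path(_draw(state, eps, not entrance_only), mu_k[region])
        if kind == 0:
            t, outward = _sphere_distance(px, py, pz, ux, uy, uz, edges[region], edges[region + 1])
        else:
            t, outward = _slab_distance(pz, uz, edges[region], edges[region + 1])

        if step < t:  # scattering event inside the region
            px += step * ux
            py += step * uy
            pz += step * uz
            lk[region] += step
            total += step
            cos_s = _hg_cosine(_draw(state, eps, not entrance_only), g_k[region])
            phi_s = 2.0 * np.pi * _draw(state, eps, not entrance_only)
            if mutation == 2:
                # defective sampler: azimuth missing its factor of two,
                # so the scattering kernel no longer preserves isotropy
                phi_s *= 0.5
            ux, uy, uz = _rotate(ux, uy, uz, cos_s, phi_s)
            n_scat += 1
            continue

        if not np.isfinite(t):  # uz == 0 in a non-scattering slab layer
            capped = True
            break

        # interface event
        px += t * ux
        py += t * uy
        pz += t * uz
        lk[region] += t
        total += t
        n_bound += 1

        if kind == 0:
            # snap the radius onto the interface to stop drift
            r_if = edges[region] if outward else edges[region + 1]
            rho = np.sqrt(px * px + py * py + pz * pz)
            if rho > 0.0:
                scale = r_if / rho
                px *= scale
                py *= scale
                pz *= scale
            inv = 1.0 / r_if
            if outward:
                nx, ny, nz = px * inv, py * inv, pz * inv
            else:
                nx, ny, nz = -px * inv, -py * inv, -pz * inv
            exits = outward and region == 0
            nbr = region - 1 if outward else region + 1
        else:
            pz = edges[region + 1] if outward else edges[region]
            nz = 1.0 if outward else -1.0
            nx, ny = 0.0, 0.0
            exits = (outward and region == n_regions - 1) or (not outward and region == 0)
            nbr = region + 1 if outward else region - 1

        n_to = n_e if exits else n_k[nbr]
        cos_i = ux * nx + uy * ny + uz * nz
        if cos_i > 1.0:
            cos_i = 1.0
        if mutation == 1:
            # boundary treatment disabled: always transmit; at TIR the
            # photon passes straight through unbent
            ok, tx, ty, tz = _refract(ux, uy, uz, nx, ny, nz, n_k[region], n_to)
            if ok:
                ux, uy, uz = tx, ty, tz
            if exits:
                break
            region = nbr
        else:
            refl = _fresnel(cos_i, n_k[region], n_to)
            if _draw(state, eps, not entrance_only) < refl:
                ux, uy, uz = _reflect(ux, uy, uz, nx, ny, nz)
            else:
                ok, tx, ty, tz = _refract(ux, uy, uz, nx, ny, nz, n_k[region], n_to)
                if not ok:
                    # unreachable: TIR gives refl = 1, so we never get here
                    ux, uy, uz = _reflect(ux, uy, uz, nx, ny, nz)
                else:
                    ux, uy, uz = tx, ty, tz
                    if exits:
                        break
                    region = nbr

        if max_events > 0 and n_bound >= max_events:
            capped = True
            break

    return total, n_scat, n_bound, True, capped


@njit(cache=True)
def _run_kernel(
    kind,
    edges,
    n_k,
    mu_k,
    g_k,
    n_e,
    n_photons,
    seed,
    eps,
    entrance_only,
    mutation,
    max_events,
    hist_counts,
    hist_width,
    record,
    paths_out,
):
    n_regions = n_k.shape[0]
    state = np.empty(4, dtype=np.uint64)
    lk = np.empty(n_regions, dtype=np.float64)
    sum_L = 0.0
    sum_L2 = 0.0
    sum_lk = np.zeros(n_regions, dtype=np.float64)
    sum_lk2 = np.zeros(n_regions, dtype=np.float64)
    n_entered = 0
    n_capped = 0
    n_scat_total = 0
    n_bins = hist_counts.shape[0]
    for i in range(n_photons):
        init_state(state, seed, i)
        L, n_scat, n_bound, entered, capped = _trace_one(
            kind, edges, n_k, mu_k, g_k, n_e, state, i, eps, entrance_only,
            mutation, max_events, lk,
        )
        sum_L += L
        sum_L2 += L * L
        for r in range(n_regions):
            sum_lk[r] += lk[r]
            sum_lk2[r] += lk[r] * lk[r]
        if entered:
            n_entered += 1
        if capped:
            n_capped += 1
        n_scat_total += n_scat
        if n_bins > 0 and L > 0.0:
            b = int(L / hist_width)
            if b < n_bins:
                hist_counts[b] += 1
        if record:
            paths_out[i] = L
    return sum_L, sum_L2, sum_lk, sum_lk2, n_entered, n_capped, n_scat_total


# --------------------------------------------------------------------------
# Python-facing API
# --------------------------------------------------------------------------


def launch_photon(medium: LayeredMedium, stream, photon_index: int = 0) -> PhotonState:
    """Launch one photon: Lambertian entrance angle, entry Fresnel drawn
    stochastically, Snell-refracted inward direction on success.

    ``stream`` is a RandomStream; a refused photon is returned with
    ``entered=False`` (it still counts in ensemble averages, with L=0).
    """
    kind_code, edges, n_k, mu_k, g_k = medium.as_arrays()
    state = stream._state
    rec = _trace_launch_py(kind_code, edges, n_k, medium.n_external, state, photon_index)
    return rec


def _trace_launch_py(kind_code, edges, n_k, n_e, state, photon_index):
    # mirror of the kernel launch block, at Python level for inspection
    n_regions = n_k.shape[0]
    xi_theta = next_uniform(state)
    cos_e = np.sqrt(1.0 - xi_theta)
    sin_e = np.sqrt(xi_theta)
    phi = 2.0 * np.pi * next_uniform(state)
    if kind_code == 0:
        pos = np.array([0.0, 0.0, edges[0]])
        normal = np.array([0.0, 0.0, -1.0])
        region = 1
    elif photon_index % 2 == 0:
        pos = np.zeros(3)
        normal = np.array([0.0, 0.0, 1.0])
        region = 1
    else:
        pos = np.array([0.0, 0.0, edges[n_regions]])
        normal = np.array([0.0, 0.0, -1.0])
        region = n_regions
    n_first = n_k[region - 1]
    refused = next_uniform(state) < _fresnel(cos_e, n_e, n_first)
    direction = np.array(
        [sin_e * np.cos(phi), sin_e * np.sin(phi), cos_e * normal[2]]
    )
    if not refused:
        ok, ux, uy, uz = _refract(
            direction[0], direction[1], direction[2], normal[0], normal[1], normal[2], n_e, n_first
        )
        refused = not ok
        if ok:
            direction = np.array([ux, uy, uz])
    return PhotonState(
        position=pos,
        direction=direction,
        region=region,
        partial_paths=np.zeros(n_regions),
        entered=not refused,
    )


def simulate_photon(
    medium: LayeredMedium,
    seed: int,
    photon_index: int = 0,
    max_boundary_events: int = 0,
    rng_quantization_eps: float = 0.0,
    entrance_only: bool = False,
    mutation: str = "none",
) -> TrajectoryRecord:
    """Trace a single photon with its deterministic substream."""
    kind_code, edges, n_k, mu_k, g_k = medium.as_arrays()
    state = np.empty(4, dtype=np.uint64)
    init_state(state, seed, photon_index)
    lk = np.empty(medium.n_layers, dtype=np.float64)
    L, n_scat, n_bound, entered, capped = _trace_one(
        kind_code, edges, n_k, mu_k, g_k, medium.n_external, state, photon_index,
        rng_quantization_eps, entrance_only, MUTATIONS[mutation],
        max_boundary_events, lk,
    )
    return TrajectoryRecord(
        total_path=float(L),
        partial_paths=lk.copy(),
        n_scatterings=int(n_scat),
        n_boundary_events=int(n_bound),
        entered=bool(entered),
        capped=bool(capped),
    )


def run_ensemble(
    medium: LayeredMedium,
    n_photons: int,
    seed: int,
    max_boundary_events: int = 0,
    rng_quantization_eps: float = 0.0,
    entrance_only: bool = False,
    mutation: str = "none",
    histogram_bins: int = 0,
    histogram_bin_width: float = 0.1,
    record_paths: bool = False,
) -> EnsembleTallies:
    """Simulate ``n_photons`` trajectories and return streaming tallies.

    Every photon uses a deterministic substream of ``seed`` keyed by its
    index, so results are independent of batching.  ``n`` counts all
    launched photons, including those refused at the surface (L = 0).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if mutation not in MUTATIONS:
        raise ValueError(f"unknown mutation {mutation!r}")
    kind_code, edges, n_k, mu_k, g_k = medium.as_arrays()
    hist = np.zeros(histogram_bins, dtype=np.int64)
    paths = np.empty(n_photons if record_paths else 0, dtype=np.float64)
    sum_L, sum_L2, sum_lk, sum_lk2, n_entered, n_capped, n_scat = _run_kernel(
        kind_code, edges, n_k, mu_k, g_k, medium.n_external,
        n_photons, seed, rng_quantization_eps, entrance_only,
        MUTATIONS[mutation], max_boundary_events,
        hist, histogram_bin_width, record_paths, paths,
    )
    return EnsembleTallies(
        n=n_photons,
        sum_L=float(sum_L),
        sum_L2=float(sum_L2),
        sum_lk=sum_lk,
        sum_lk2=sum_lk2,
        n_entered=int(n_entered),
        n_capped=int(n_capped),
        n_scatterings=int(n_scat),
        histogram_counts=hist if histogram_bins > 0 else None,
        histogram_bin_width=histogram_bin_width if histogram_bins > 0 else None,
        paths=paths if record_paths else None,
    )


def apply_absorption_weight(
    record: TrajectoryRecord, mu_a: Sequence[float]
) -> float:
    """Beer-Lambert weight prod_k exp(-mu_a_k * l_k) for one trajectory.

    Absorption does not change trajectories; a verified non-absorbing
    engine extends to absorbing media by re-weighting each recorded
    trajectory with this factor.
    """
    mu = np.asarray(mu_a, dtype=float)
    if mu.shape != record.partial_paths.shape:
        raise ValueError("mu_a must give one coefficient per region")
    if np.any(mu < 0.0):
        raise ValueError("absorption coefficients must be >= 0")
    return float(np.exp(-(mu @ record.partial_paths)))
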