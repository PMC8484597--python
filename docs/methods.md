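# Methods

## Model

The engine simulates scalar (unpolarized) photon random walks through a
non-absorbing medium composed of homogeneous regions: concentric
spherical shells, or depth slices of a laterally-infinite slab.  Each
region carries a scattering coefficient `mu_s` (mm^-1), a
Henyey–Greenstein anisotropy `g` in (-1, 1), and a refractive index
`n`; the surrounding half-space has index `n_e`.  Between events a
photon flies in a straight line; path lengths between scattering events
are exponential with rate `mu_s` (`l = -ln(1-xi)/mu_s`, the inverse CDF
of `p(l) = mu_s exp(-mu_s l)`); `mu_s = 0` regions are ballistic (the
photon flies to the next interface).  Scattering deflects the direction
by the HG cosine, sampled through the closed-form inverse CDF, with a
uniform azimuth; HG is used precisely because its analytic inversion
removes phase-function sampling error from the error budget.  At
interfaces the photon reflects or transmits stochastically with the
unpolarized Fresnel coefficient (TIR gives R = 1); transmission applies
Snell bending.  Crossing an interface redraws the free path with the
local `mu_s` — by memorylessness of the exponential this is
statistically exact, not an approximation.  There is no absorption:
every launched photon eventually exits and is received, so the
ensemble size is non-random.  Absorption is applied afterwards by
Beer–Lambert re-weighting of each trajectory with
`prod_k exp(-mu_a_k l_k)` over its per-region partial paths.

## Illumination and the ensemble convention

Lambertian (constant-radiance) illumination draws the external polar
angle from `theta = arccos(sqrt(1 - xi))` and the azimuth uniformly.
The symmetries of the two bodies reduce uniform surface illumination to
a point: the sphere is illuminated at `(0, 0, r)`; the slab alternates
its two faces deterministically by photon parity so each face receives
exactly `N/2` photons (required for asymmetric layer profiles; for the
laterally-infinite slab, point illumination is the only implementable
option anyway).

Photons Fresnel-refused at first incidence are counted in the ensemble
with `L = 0`.  This all-incident convention is what makes the sample
mean converge to `4 (V/S) n_r^2` exactly: Snell's law maps the external
cosine-law angular density onto the internal one with Jacobian `n_r^2`,
and Fresnel reciprocity makes the entry refusals balance the internal
escape refusals.  The package's ballistic mismatched-slab oracle
(`tests/test_transport.py`) checks this closed form against an
independent quadrature over the entry law with geometric
internal-bounce counts.

## Invariance references and the verification protocol

The references take no scattering arguments at all — by construction
they cannot depend on `mu_s` or `g`:

* 3D total: `<L>_IP = 4 (V/S) n_r^2` (sphere `V/S = r/3`; slab
  `V/S = d/2` per unit illuminated area, counting both faces, so the
  matched slab reference is `2d`);
* per-region: `<L_k>_IP = 4 (n_k/n_e)^2 V_k/S`, summing to the total;
* 2D analogue `pi (S/P) n_r` is provided as a reference function only.

Validity: for non-ergodic bodies (sphere, slab) a region with
`n_k > n_e` must have `mu_s > 0`; otherwise guided (totally internally
reflected) ballistic trajectories exist, `<L_k>` is discontinuous at
`mu_s = 0`, and the invariant does not apply.  The package warns and
continues, since the discontinuity is physics rather than an error.

Verification of a run tests the total and every per-layer mean against
its invariant with a one-sample Student t (N-1 degrees of freedom,
two-tailed by default; standard error `sigma_L/sqrt(N)` with the N-1
variance denominator).  No multiplicity correction is applied to the
individual tests; instead the report compares the observed number of
5%-level rejections with the `m * alpha` expected by chance, using an
exact binomial test at the 1% level.  The overall verdict is PASS iff
that count is compatible and no trajectory hit the optional
boundary-event cap (any capped trajectory invalidates a verification
run and is reported loudly).  The cap itself is off by default; it
exists to guard pathological guided-mode configurations, never to trim
the path-length distribution.

## Random numbers and precision emulation

Uniform deviates come from xoshiro256++ seeded via splitmix64 from the
pair (run seed, photon index), giving every photon a deterministic
substream: results are bit-reproducible and independent of batching or
execution order.  Deviates carry the full 53-bit double mantissa.

Reduced-precision generators are emulated by a floor-grid wrapper
`xi -> floor(xi/eps) * eps`, applied to all deviates or (to isolate the
mechanism) only to the entrance-angle deviate.  The single-precision
grid is `eps = 2^-23`: its maximum deviate `1 - 2^-23` reproduces the
limiting entrance angle `arccos(sqrt(2^-23)) = 1.570451` rad and the
missing-tail bias `-2 d sqrt(eps) = -0.0069` mm for the 10 mm ballistic
slab.  The double-precision emulation grid defaults to
`eps = 1.218e-13` (entrance angle 1.570796 rad, bias -6.98e-6 mm) and
is configurable.  Closed forms provided: the maximum entrance angle,
the tail-truncation bias `b = -2 d sqrt(eps)`, the truncated variance
`sigma_L^2 = d^2 ln(1/eps) - 4 d^2 (1 - sqrt(eps))^2`, and the
detection statistic `t = b sqrt(N)/sigma_L` (about -2.0 at `N = 1e8`
for single precision; -4.35 at `N = 1e15` for the double-precision
grid).

A numerical point the diagnostics account for: the engine's measured
bias under full floor-grid quantization is not the pure tail value.
The grid also shifts every non-tail deviate down by `eps/2` on average,
which adds a smooth Riemann term of about `-(d/2) sqrt(eps)` to the
net tail contribution `-d sqrt(eps)`; the exact grid sum gives
-0.00504 mm at `eps = 2^-23`, between the tail-truncation bound and
half of it.  Consequently engine-level one-tailed detection becomes
reliable at `N = 1e9` trajectories (expected z about -4.6), and the
acceptance test runs the detection experiment at that size; the
closed-form `t = -2` at `N = 1e8` describes the tail-only model.

## Fault injection

Three mutations exercise the method's sensitivity, each a realistic bug
class:

* `no_fresnel` — boundary treatment disabled: photons always transmit,
  and where no refracted direction exists (TIR) they pass straight
  through unbent;
* `biased_hg` — the scattering azimuth misses its factor of two
  (`phi` in `[0, pi)`), producing a scattering kernel that no longer
  preserves isotropy;
* `truncated_lambertian` — the entrance-angle deviate is capped at
  0.75 (`theta_in <= 60` degrees), a crude illumination error.

All three flip the verification verdict to FAIL on the 4-layer
mismatched sphere at `N = 1e6`.  One deliberate subtlety: the invariant
is provably insensitive to any *valid* phase function, so a mutation
that merely reshapes the deflection-cosine distribution (while still
sampling a proper density with uniform azimuth) is undetectable in
principle — that insensitivity is the method's one structural blind
spot, and it is why the injected sampler bug breaks isotropy
preservation rather than the HG shape.  Likewise, removing Fresnel
*reflection* while keeping TIR and Snell refraction turns out to leave
the invariant intact (it is still a reciprocal boundary model), which
is why the `no_fresnel` mutation removes the boundary treatment
outright.

## Numerical choices

* Ray–sphere intersections solve the quadratic in the q-formulation to
  avoid cancellation near tangency; candidate distances below 1e-12 mm
  are discarded (the photon is sitting on that interface).
* The current region is tracked explicitly as an index updated at
  crossings, never re-inferred from coordinates; positions are snapped
  onto the interface radius/plane after each crossing to stop
  floating-point drift.
* The free-path inversion uses `-ln(1-xi)` with `xi` in [0, 1) (never
  `ln(0)`); `-ln(xi)` would be equivalent in law, but the 1-xi branch
  is the one the quantization diagnostics reason about.
* The direction-rotation update renormalizes and has a degenerate
  branch for |u_z| within 1e-12 of 1; unit norm is preserved to 1e-10
  over arbitrarily long trajectories.
* A slab photon with exactly horizontal direction in a ballistic layer
  can never reach an interface; it is terminated and counted as capped
  (probability zero in exact arithmetic, and never observed in the test
  runs).
* Streaming first and second moments (Kahan-free plain sums in double
  precision) are exact to well below the statistical error at the
  ensemble sizes used (up to 1e9 photons, path lengths of order 10 mm).

## Fixtures and what the synthetic media do (and do not) cover

The built-in media are the canonical verification set: a homogeneous
sphere (r = 5 mm) and slab (d = 10 mm) with free `mu_s`, `g`, `n_r`;
the 4-layer sphere (interfaces at 4, 3, 2 mm, indices
1.75/1.5/1.25/1.0 in external index 2, scattering only in alternating
layers); and three 100-layer profiles in external index 2 — a sphere
with `n_k = 2 - 0.01 k` (0.5 mm core, 99 equal shells above it, the
shell thicknesses being this package's discretization choice), a slab
with the same monotone profile, and a slab with the mirrored profile
`n_1 = n_100 = 1.98`, `n_50 = n_51 = 1.00`.  The 100-layer media
default to `mu_s = 0`, which is valid because every `n_k < n_e`.

These synthetic media exercise refraction, TIR, layered partial-path
accounting and eight decades of scattering, but they are ideal layered
geometries: passing the suite says nothing about voxelized or meshed
anatomies, spatially-resolved or time-resolved detection, polarization,
or inelastic processes, all of which are out of scope.  And per the
blind spot above, the invariance check cannot vouch for the *shape* of
the phase function — only for boundaries, path accounting, the
entrance law and the step-length law.

## Problem sizes

The shipped verification suite uses desk-scale ensembles chosen so the
whole battery runs on one CPU core in minutes: 1e6 trajectories per
grid cell for the Monte Carlo/invariance consistency grids and mutation
tests, 1e5 for the ballistic density oracles, 1e4 vs 1e8 for the
error-scaling check, and 1e9 for the RNG-precision detection run.  At
these sizes the invariant is verified to 3-4 significant digits per
cell; the protocol itself is accuracy-unlimited — the standard error
falls as `1/sqrt(N)`, so six-digit verification is a matter of running
1e10 or more trajectories on bigger hardware, not of changing the
method.
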