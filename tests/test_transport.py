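import numpy as np
import pytest
from scipy import integrate

from meanpath import (
    RandomStream,
    apply_absorption_weight,
    build_fixture,
    run_ensemble,
    simulate_photon,
    summarize,
)
from meanpath.geometry import LayerSpec, LayeredMedium
from meanpath.transport import launch_photon


def ballistic_slab(d=10.0, n=1.0, n_e=1.0, mu_s=0.0):
    return LayeredMedium("slab", n_e, (LayerSpec(1, 0.0, d, n, mu_s),))


class TestSinglePhoton:
    def test_ballistic_sphere_chord(self, sphere_r5):
        """mu_s=0, matched: L is the chord 2 r cos(theta_in)."""
        for idx in range(20):
            rec = simulate_photon(sphere_r5, seed=9, photon_index=idx)
            xi = RandomStream(9, idx).uniform()  # the entrance-angle deviate
            assert rec.entered
            assert rec.total_path == pytest.approx(10.0 * np.sqrt(1.0 - xi), rel=1e-9)

    def test_ballistic_slab_secant(self, slab_d10):
        for idx in range(20):
            rec = simulate_photon(slab_d10, seed=9, photon_index=idx)
            xi = RandomStream(9, idx).uniform()
            assert rec.total_path == pytest.approx(10.0 / np.sqrt(1.0 - xi), rel=1e-9)

    def test_partial_paths_sum_to_total(self, table2_sphere):
        for idx in range(200):
            rec = simulate_photon(table2_sphere, seed=13, photon_index=idx)
            assert np.all(rec.partial_paths >= 0.0)
            if rec.entered:
                assert rec.total_path == pytest.approx(
                    rec.partial_paths.sum(), rel=1e-9
                )
            else:
                assert rec.total_path == 0.0

    def test_refused_photon_has_zero_path(self):
        # n_e=2 into n=1: normal-ish incidence R = 1/9; find a refused index
        m = ballistic_slab(n=1.0, n_e=2.0)
        refused = [
            simulate_photon(m, seed=1, photon_index=i)
            for i in range(200)
        ]
        assert any(not r.entered for r in refused)
        for r in refused:
            if not r.entered:
                assert r.total_path == 0.0
                assert r.n_boundary_events == 0


class TestLaunch:
    def test_matched_always_enters_inward(self, sphere_r5):
        stream = RandomStream(21)
        for i in range(50):
            state = launch_photon(sphere_r5, stream, photon_index=i)
            assert state.entered
            # inward at the entry point (0,0,r): negative z-component
            assert state.direction[2] < 0.0
            assert np.linalg.norm(state.direction) == pytest.approx(1.0, abs=1e-10)

    def test_slab_side_alternation(self, slab_d10):
        stream = RandomStream(22)
        even = launch_photon(slab_d10, stream, photon_index=0)
        odd = launch_photon(slab_d10, stream, photon_index=1)
        assert even.position[2] == 0.0 and even.direction[2] > 0.0
        assert odd.position[2] == 10.0 and odd.direction[2] < 0.0


class TestEnsemble:
    def test_conservation_no_photon_lost(self, table2_sphere):
        tallies = run_ensemble(table2_sphere, 20_000, seed=3)
        assert tallies.n == 20_000
        assert tallies.n_capped == 0
        assert tallies.n_entered <= tallies.n

    def test_matched_medium_all_photons_enter(self, sphere_r5):
        tallies = run_ensemble(sphere_r5, 10_000, seed=4)
        assert tallies.n_entered == tallies.n

    def test_batching_invariance(self, table2_sphere):
        """Per-photon substreams: one run of 2N equals two runs of N."""
        full = run_ensemble(table2_sphere, 2_000, seed=5)
        a = sum(
            simulate_photon(table2_sphere, seed=5, photon_index=i).total_path
            for i in range(2_000)
        )
        assert full.sum_L == pytest.approx(a, rel=1e-12)

    def test_boundary_event_cap_reported(self):
        m = build_fixture("sphere_homog_r5", mu_s=1.0, n_r=2.0)
        tallies = run_ensemble(m, 5_000, seed=6, max_boundary_events=2)
        assert tallies.n_capped > 0

    def test_mismatched_ballistic_slab_matches_brute_force(self):
        """Independent oracle: expectation over the Lambertian entry law
        with Fresnel entry, Snell bending and geometric internal-bounce
        counts.  It reproduces 2 d n_r^2 exactly; the engine must agree
        within sampling error."""
        d, n, n_e = 10.0, 1.0, 1.5
        n_r = n / n_e

        def integrand(xi):
            sin_e2 = xi
            sin_i2 = sin_e2 / n_r**2
            if sin_i2 >= 1.0:
                return 0.0  # total external reflection: never enters
            cos_e = np.sqrt(1.0 - sin_e2)
            cos_i = np.sqrt(1.0 - sin_i2)
            rs = (n_e * cos_e - n * cos_i) / (n_e * cos_e + n * cos_i)
            rp = (n * cos_e - n_e * cos_i) / (n * cos_e + n_e * cos_i)
            T = 1.0 - 0.5 * (rs * rs + rp * rp)
            # enter w.p. T; geometric number of internal segments, mean 1/T
            return T * (1.0 / T) * (d / cos_i)

        oracle, _ = integrate.quad(integrand, 0.0, n_r**2, limit=200)
        assert oracle == pytest.approx(2.0 * d * n_r**2, rel=1e-9)

        tallies = run_ensemble(ballistic_slab(d, n, n_e), 400_000, seed=8)
        s = summarize(tallies)
        assert abs(s.mean - oracle) < 4.0 * s.standard_error


class TestAbsorptionWeight:
    def test_closed_form(self):
        from meanpath.transport import TrajectoryRecord

        rec = TrajectoryRecord(
            total_path=3.0,
            partial_paths=np.array([1.0, 2.0]),
            n_scatterings=0,
            n_boundary_events=1,
            entered=True,
        )
        assert apply_absorption_weight(rec, [0.1, 0.2]) == pytest.approx(
            np.exp(-0.5), rel=1e-12
        )

    def test_no_absorption_is_unit_weight(self, table2_sphere):
        rec = simulate_photon(table2_sphere, seed=2, photon_index=0)
        assert apply_absorption_weight(rec, [0.0] * 4) == 1.0

    def test_multiplicativity(self, table2_sphere):
        rec = simulate_photon(table2_sphere, seed=2, photon_index=3)
        mu1 = np.array([0.1, 0.0, 0.3, 0.2])
        mu2 = np.array([0.05, 0.4, 0.0, 0.1])
        assert apply_absorption_weight(rec, mu1 + mu2) == pytest.approx(
            apply_absorption_weight(rec, mu1) * apply_absorption_weight(rec, mu2),
            rel=1e-12,
        )

    def test_negative_mu_a_rejected(self, table2_sphere):
        rec = simulate_photon(table2_sphere, seed=2, photon_index=0)
        with pytest.raises(ValueError):
            apply_absorption_weight(rec, [-0.1, 0.0, 0.0, 0.0])
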