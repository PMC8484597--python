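import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from meanpath.geometry import (
    LayerSpec,
    LayeredMedium,
    distance_to_interface,
    interface_normal,
    layer_volume_ratio,
)


def sphere_from_radii(radii_desc, n=1.0, mu_s=0.0):
    layers = [
        LayerSpec(index=i + 1, inner=radii_desc[i + 1], outer=radii_desc[i], n=n, mu_s=mu_s)
        for i in range(len(radii_desc) - 1)
    ]
    return LayeredMedium("sphere", 1.0, tuple(layers))


def slab_from_edges(edges, n=1.0, mu_s=0.0):
    layers = [
        LayerSpec(index=i + 1, inner=edges[i], outer=edges[i + 1], n=n, mu_s=mu_s)
        for i in range(len(edges) - 1)
    ]
    return LayeredMedium("slab", 1.0, tuple(layers))


class TestLayerVolumeRatio:
    def test_outer_shell_of_table2_sphere(self):
        m = sphere_from_radii([5.0, 4.0, 0.0])
        assert layer_volume_ratio(m, 1) == pytest.approx(61.0 / 75.0, rel=1e-12)

    def test_single_layer_sphere_is_r_over_3(self):
        m = sphere_from_radii([5.0, 0.0])
        assert layer_volume_ratio(m, 1) == pytest.approx(5.0 / 3.0, rel=1e-12)

    def test_single_layer_slab_is_d_over_2(self):
        m = slab_from_edges([0.0, 10.0])
        assert layer_volume_ratio(m, 1) == pytest.approx(5.0, rel=1e-12)

    def test_invalid_layer_index(self):
        m = sphere_from_radii([5.0, 0.0])
        with pytest.raises(IndexError):
            layer_volume_ratio(m, 2)

    @given(
        cuts=st.lists(
            st.floats(0.05, 0.95).map(lambda x: round(x, 2)),
            min_size=0,
            max_size=8,
            unique=True,
        ),
        kind=st.sampled_from(["sphere", "slab"]),
        scale=st.floats(0.5, 50.0),
    )
    def test_ratios_sum_to_whole_body_ratio(self, cuts, kind, scale):
        """Partition additivity: sum_k V_k/S = r/3 (sphere) or d/2 (slab)."""
        edges = sorted({0.0, 1.0, *cuts})
        edges = [e * scale for e in edges]
        if kind == "sphere":
            m = sphere_from_radii(list(reversed(edges)))
            expected = scale / 3.0
        else:
            m = slab_from_edges(edges)
            expected = scale / 2.0
        total = sum(layer_volume_ratio(m, k) for k in range(1, m.n_layers + 1))
        assert total == pytest.approx(expected, rel=1e-12)
        assert total == pytest.approx(m.volume_surface_ratio(), rel=1e-12)


class TestDistanceToInterface:
    def test_diameter_chord(self):
        m = sphere_from_radii([5.0, 0.0])
        d, iid, outward = distance_to_interface(
            np.array([0.0, 0.0, 5.0]), np.array([0.0, 0.0, -1.0]), 1, m
        )
        assert d == pytest.approx(10.0, abs=1e-12)
        assert iid == 0 and outward

    def test_radius_from_center(self):
        m = sphere_from_radii([5.0, 0.0])
        u = np.array([1.0, 2.0, -2.0]) / 3.0
        d, _, _ = distance_to_interface(np.zeros(3), u, 1, m)
        assert d == pytest.approx(5.0, abs=1e-12)

    def test_slab_oblique_crossing(self):
        m = slab_from_edges([0.0, 10.0])
        u = np.array([np.sqrt(0.75), 0.0, 0.5])
        d, iid, outward = distance_to_interface(np.zeros(3), u, 1, m)
        assert d == pytest.approx(20.0, abs=1e-12)
        assert iid == 1 and outward

    def test_slab_ignores_lateral_position(self):
        m = slab_from_edges([0.0, 10.0])
        u = np.array([0.6, 0.0, 0.8])
        d0, _, _ = distance_to_interface(np.array([0.0, 0.0, 1.0]), u, 1, m)
        d1, _, _ = distance_to_interface(np.array([1e6, -3e5, 1.0]), u, 1, m)
        assert d0 == d1

    def test_inner_shell_boundary_reached_going_inward(self):
        m = sphere_from_radii([5.0, 4.0, 0.0])
        d, iid, outward = distance_to_interface(
            np.array([0.0, 0.0, 5.0]), np.array([0.0, 0.0, -1.0]), 1, m
        )
        assert d == pytest.approx(1.0, abs=1e-12)
        assert iid == 1 and not outward

    def test_region_advance_is_always_positive(self):
        """Repeated boundary-to-boundary stepping never stalls: a photon
        sitting on its region's outer bound heads inward (and vice
        versa), as after any transmit event, and always advances."""
        m = sphere_from_radii([5.0, 3.0, 1.0, 0.0])
        rng = np.random.default_rng(42)
        pos = np.array([0.0, 0.0, 5.0])
        region = 1
        for _ in range(200):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            layer = m.layers[region - 1]
            rho = np.linalg.norm(pos)
            if abs(rho - layer.outer) < 1e-9 and pos @ u > 0:
                u = -u  # entering through the outer bound: head inward
            elif abs(rho - layer.inner) < 1e-9 and pos @ u < 0:
                u = -u  # entering through the inner bound: head outward
            d, iid, outward = distance_to_interface(pos, u, region, m)
            assert d > 0.0
            pos = pos + d * u
            # snap and move to the neighbouring region (transmit always)
            r_if = layer.outer if outward else layer.inner
            pos *= r_if / np.linalg.norm(pos)
            region = region - 1 if outward else region + 1
            if region == 0:  # exited; relaunch from the surface point inward
                region = 1


class TestInterfaceNormal:
    def test_sphere_inward_normal(self, table2_sphere):
        n = interface_normal(table2_sphere, 1, np.array([0.0, 0.0, 4.0]), outward=False)
        assert np.allclose(n, [0.0, 0.0, -1.0])

    def test_slab_entry_face_normal(self, slab_d10):
        n = interface_normal(slab_d10, 0, np.array([0.0, 0.0, 0.0]), outward=False)
        assert np.allclose(n, [0.0, 0.0, -1.0])

    def test_unit_norm(self, table2_sphere):
        p = np.array([1.0, 2.0, 2.0]) / 3.0 * 4.0
        n = interface_normal(table2_sphere, 1, p, outward=True)
        assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-12)


class TestValidation:
    def test_gap_between_layers_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            LayeredMedium(
                "sphere",
                1.0,
                (
                    LayerSpec(1, 4.0, 5.0, 1.0, 0.0),
                    LayerSpec(2, 0.0, 3.0, 1.0, 0.0),
                ),
            )

    def test_sphere_must_reach_center(self):
        with pytest.raises(ValueError, match="radius 0"):
            LayeredMedium("sphere", 1.0, (LayerSpec(1, 1.0, 5.0, 1.0, 0.0),))

    def test_bad_layer_parameters(self):
        with pytest.raises(ValueError):
            LayerSpec(1, 5.0, 4.0, 1.0, 0.0)  # outer < inner
        with pytest.raises(ValueError):
            LayerSpec(1, 0.0, 5.0, 1.0, -0.1)  # negative mu_s
        with pytest.raises(ValueError):
            LayerSpec(1, 0.0, 5.0, 1.0, 0.0, g=1.0)  # |g| >= 1
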