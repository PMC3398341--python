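import numpy as np
import pytest

from heartnc.adaptation import (
    ChannelState,
    NodeWeights,
    adapt_field,
    adapt_lateral,
    adapt_longitudinal,
    compute_node_weights,
    partition_regions,
    reconstruct,
)
from heartnc.errors import ConfigurationError, GeometryError
from heartnc.geometry_core import DeformationField, apply_field
from heartnc.navigator import CHANNEL_ROLES, NavigatorChannel
from heartnc.phantom import HeartPhantomParams, generate_heart

BBOX = (-4.0, 4.0, 2.0, 12.0)  # x_min, x_max, y_min, y_max


def make_channels(mesh):
    """Six channel rectangles laid out on a mesh's radiograph-plane bbox."""
    lo, hi = mesh.bbox()
    y_u = lo[1] + 0.3 * (hi[1] - lo[1])
    y_l = lo[1] + 0.7 * (hi[1] - lo[1])
    cx = 0.5 * (lo[0] + hi[0])
    return [
        NavigatorChannel("NC1", (lo[0], y_l), (2.0, 0.5), "horizontal"),
        NavigatorChannel("NC2", (hi[0], y_l), (2.0, 0.5), "horizontal"),
        NavigatorChannel("NC3", (lo[0], y_u), (2.0, 0.5), "horizontal"),
        NavigatorChannel("NC4", (hi[0], y_u), (2.0, 0.5), "horizontal"),
        NavigatorChannel("NC5", (cx, lo[1]), (0.5, 4.0), "vertical"),
        NavigatorChannel("NC6", (cx, hi[1]), (0.5, 4.0), "vertical"),
    ]


def states(**shifts):
    """All-channel states with given shifts (default 0) and fixed deltas."""
    deltas = {"NC1": -0.8, "NC2": 0.9, "NC3": -0.6, "NC4": 0.7, "NC5": 1.1, "NC6": -1.0}
    return {
        role: ChannelState(role, deltas[role], float(shifts.get(role, 0.0)))
        for role in CHANNEL_ROLES
    }


class TestNodeWeights:
    def test_superior_right_corner(self):
        w = compute_node_weights((-4.0, 2.0, 0.0), BBOX)
        assert (w.k_x, w.k_y) == (0.0, 0.0)

    def test_center(self):
        w = compute_node_weights((0.0, 7.0, 0.0), BBOX)
        assert (w.k_x, w.k_y) == (0.5, 0.5)

    def test_clamping(self):
        w = compute_node_weights((10.0, -5.0, 0.0), BBOX)
        assert (w.k_x, w.k_y) == (1.0, 0.0)

    def test_degenerate_bbox(self):
        with pytest.raises(GeometryError):
            compute_node_weights((0, 0, 0), (1.0, 1.0, 2.0, 12.0))


class TestAdaptLongitudinal:
    def test_zero_shifts_identity(self):
        s = states()
        out = adapt_longitudinal(0.7, NodeWeights(0.5, 0.3), s["NC5"], s["NC6"])
        assert out == 0.7

    def test_hand_evaluated_value(self):
        # delta_y = 1.0, sup channel (2.0, +0.5), inf channel (1.0, +0.2),
        # equal weights: 1.0 * (0.5*2.5/2.0 + 0.5*1.2/1.0) = 1.225
        sup = ChannelState("NC5", 2.0, 0.5)
        inf = ChannelState("NC6", 1.0, 0.2)
        out = adapt_longitudinal(1.0, NodeWeights(0.5, 0.5), sup, inf)
        assert out == pytest.approx(1.225, abs=1e-12)

    def test_equal_ratios_any_weight(self):
        # both channels scale by r = 1.3 -> output r * delta for any k_y
        sup = ChannelState("NC5", 2.0, 0.6)
        inf = ChannelState("NC6", -1.0, -0.3)
        for ky in (0.0, 0.25, 0.8, 1.0):
            out = adapt_longitudinal(0.9, NodeWeights(0.5, ky), sup, inf)
            assert out == pytest.approx(1.3 * 0.9, abs=1e-12)

    def test_epsilon_fallback_additive(self):
        sup = ChannelState("NC5", 0.0, 0.4)
        inf = ChannelState("NC6", 1.0, 0.0)
        out = adapt_longitudinal(0.5, NodeWeights(0.5, 0.0), sup, inf)
        assert out == pytest.approx(0.5 + 1.0 * 0.4, abs=1e-12)


class TestAdaptLateral:
    def test_zero_shifts_identity_all_regions(self):
        s = states()
        for region in ("upper", "middle", "lower"):
            out = adapt_lateral(0.45, NodeWeights(0.3, 0.6), region, s)
            assert out == 0.45

    def test_middle_bilinear_degeneracy(self):
        # all four ratios equal r -> r * delta regardless of weights
        r = 1.25
        s = {
            role: ChannelState(role, d, d * (r - 1.0))
            for role, d in (("NC1", -0.8), ("NC2", 0.9), ("NC3", -0.6), ("NC4", 0.7))
        }
        for kx, ky in ((0.1, 0.9), (0.5, 0.5), (0.8, 0.2)):
            out = adapt_lateral(0.6, NodeWeights(kx, ky), "middle", s, k_y_lateral=ky)
            assert out == pytest.approx(r * 0.6, abs=1e-12)

    def test_middle_limit_equals_lower_formula(self):
        s = states(NC1=0.3, NC2=-0.2, NC3=0.1, NC4=0.4)
        for kx in (0.0, 0.3, 0.7, 1.0):
            w = NodeWeights(kx, 1.0)
            mid = adapt_lateral(0.5, w, "middle", s, k_y_lateral=1.0)
            low = adapt_lateral(0.5, w, "lower", s)
            assert mid == pytest.approx(low, abs=1e-12)

    def test_unknown_region(self):
        with pytest.raises(ConfigurationError):
            adapt_lateral(0.5, NodeWeights(0.5, 0.5), "apex", states())


class TestPartitionRegions:
    def test_examples(self):
        mesh = generate_heart(HeartPhantomParams(center=(0.0, 10.0, 0.0)))
        chans = [
            NavigatorChannel("NC3", (-4.0, 5.0), (2.0, 0.5), "horizontal"),
            NavigatorChannel("NC4", (4.0, 5.0), (2.0, 0.5), "horizontal"),
            NavigatorChannel("NC1", (-4.0, 15.0), (2.0, 0.5), "horizontal"),
            NavigatorChannel("NC2", (4.0, 15.0), (2.0, 0.5), "horizontal"),
        ]
        part = partition_regions(mesh, chans)
        y = mesh.vertices[:, 1]
        assert set(np.unique(part.labels)) <= {"upper", "middle", "lower"}
        assert all(part.labels[y < 5.0] == "upper")
        assert all(part.labels[y > 15.0] == "lower")
        assert all(part.labels[(y > 5.0) & (y < 15.0)] == "middle")

    def test_brute_force_threshold_oracle(self, rng):
        mesh = generate_heart(HeartPhantomParams(center=(0.0, 10.0, 0.0)))
        chans = make_channels(mesh)
        part = partition_regions(mesh, chans)
        for v, label in zip(mesh.vertices, part.labels):
            if v[1] < part.upper_boundary_y:
                assert label == "upper"
            elif v[1] > part.lower_boundary_y:
                assert label == "lower"
            else:
                assert label == "middle"

    def test_row_order_enforced(self):
        mesh = generate_heart(HeartPhantomParams())
        chans = make_channels(mesh)
        flipped = [
            NavigatorChannel(
                {"NC1": "NC3", "NC2": "NC4", "NC3": "NC1", "NC4": "NC2"}.get(c.role, c.role),
                c.center, c.size, c.orientation,
            )
            for c in chans
        ]
        with pytest.raises(ConfigurationError):
            partition_regions(mesh, flipped)


class TestAdaptField:
    @pytest.fixture
    def mesh(self):
        return generate_heart(HeartPhantomParams(center=(0.0, 10.0, 0.0)))

    @pytest.fixture
    def field(self, mesh, rng):
        return DeformationField(rng.normal(scale=0.5, size=(mesh.n_vertices, 3)))

    def test_zero_shifts_bit_identical(self, mesh, field):
        out = adapt_field(field, mesh, states(), make_channels(mesh))
        assert np.array_equal(out.displacements, field.displacements)

    def test_uniform_longitudinal_scaling(self, mesh):
        # identical delta d and shift s on both vertical channels scales
        # every y-displacement by (d + s) / d
        d, s = 1.5, 0.3
        st = states(NC5=s, NC6=s)
        st["NC5"] = ChannelState("NC5", d, s)
        st["NC6"] = ChannelState("NC6", d, s)
        disp = np.tile([0.0, 0.8, 0.0], (mesh.n_vertices, 1))
        out = adapt_field(DeformationField(disp), mesh, st, make_channels(mesh))
        assert np.allclose(out.displacements[:, 1], 0.8 * (d + s) / d, atol=1e-12)

    def test_z_component_preserved_exactly(self, mesh, field, rng):
        st = states(NC1=0.2, NC2=-0.1, NC3=0.15, NC4=0.05, NC5=0.3, NC6=-0.2)
        out = adapt_field(field, mesh, st, make_channels(mesh))
        assert np.array_equal(out.displacements[:, 2], field.displacements[:, 2])

    def test_missing_channel(self, mesh, field):
        st = states()
        del st["NC4"]
        with pytest.raises(ConfigurationError, match="NC4"):
            adapt_field(field, mesh, st, make_channels(mesh))

    def test_superior_role_configurable(self, mesh, field):
        st = states(NC5=0.4, NC6=-0.3)
        out5 = adapt_field(field, mesh, st, make_channels(mesh), superior_role="NC5")
        out6 = adapt_field(field, mesh, st, make_channels(mesh), superior_role="NC6")
        assert not np.array_equal(out5.displacements[:, 1], out6.displacements[:, 1])

    def test_region_boundary_continuity(self, mesh, field):
        """Nodes straddling a region row get laterally consistent values."""
        st = states(NC1=0.3, NC2=-0.2, NC3=0.1, NC4=0.4)
        chans = make_channels(mesh)
        out = adapt_field(field, mesh, st, chans)
        part = partition_regions(mesh, chans)
        lo, hi = mesh.bbox()
        bbox = (lo[0], hi[0], lo[1], hi[1])
        # evaluate both formulas for nodes within 1e-6 of the boundary k_y
        for boundary, region in (
            (part.upper_boundary_y, "upper"),
            (part.lower_boundary_y, "lower"),
        ):
            for n, v in enumerate(mesh.vertices):
                if abs(v[1] - boundary) > 0.3:
                    continue
                w = compute_node_weights(v, bbox)
                kyl = np.clip(
                    (v[1] - part.upper_boundary_y)
                    / (part.lower_boundary_y - part.upper_boundary_y),
                    0.0, 1.0,
                )
                dx = field.displacements[n, 0]
                lin = adapt_lateral(dx, w, region, st)
                mid = adapt_lateral(dx, w, "middle", st, k_y_lateral=kyl)
                # at the boundary k_y_lateral is exactly 0 or 1 and the two
                # formulas coincide; nearby they differ by O(distance)
                assert abs(mid - lin) <= 2.0 * abs(kyl - (0.0 if region == "upper" else 1.0)) * (
                    abs(dx) + 1.0
                ) + 1e-9


class TestReconstruct:
    def test_pipeline_identity(self, rng):
        population = generate_heart(HeartPhantomParams(center=(0.0, 10.0, 0.0)))
        field = DeformationField(rng.normal(scale=0.3, size=(population.n_vertices, 3)))
        deformed = apply_field(population, field)
        adapted = adapt_field(field, deformed, states(), make_channels(deformed))
        recon = reconstruct(population, adapted)
        assert np.array_equal(recon.vertices, deformed.vertices)
        assert recon.is_closed()
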