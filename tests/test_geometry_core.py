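import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from heartnc.errors import (
    ComponentError,
    EmptyInputError,
    GridMismatchError,
    IndexAlignmentError,
)
from heartnc.geometry_core import (
    BinaryMask,
    DeformationField,
    SurfaceMesh,
    apply_field,
    center_of_mass_align,
    mask_to_mesh,
    mask_union,
    mesh_to_mask,
    voxelize_on_grid,
)
from heartnc.phantom import HeartPhantomParams, generate_heart

from .conftest import make_cube_mesh

bool_grids = hnp.arrays(dtype=bool, shape=(6, 6, 6))


def mask_of(grid):
    return BinaryMask(grid, (0.1, 0.1, 0.1))


class TestMaskUnion:
    def test_disjoint_single_voxels(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = True
        b[4, 4, 4] = True
        out = mask_union([mask_of(a), mask_of(b)])
        assert np.count_nonzero(out.grid) == 2

    def test_absorption(self, rng):
        b = rng.random((8, 8, 8)) > 0.5
        a = b & (rng.random((8, 8, 8)) > 0.5)  # a subset of b
        out = mask_union([mask_of(a), mask_of(b)])
        assert np.array_equal(out.grid, b)

    def test_matches_elementwise_or_oracle(self, rng):
        grids = [rng.random((20, 20, 20)) > 0.7 for _ in range(5)]
        expected = np.zeros((20, 20, 20), bool)
        for g in grids:
            expected = expected | g  # brute-force elementwise OR
        out = mask_union([mask_of(g) for g in grids])
        assert np.array_equal(out.grid, expected)

    def test_grid_mismatch(self):
        a = mask_of(np.ones((4, 4, 4), bool))
        b = BinaryMask(np.ones((4, 4, 4), bool), (0.2, 0.2, 0.2))
        with pytest.raises(GridMismatchError):
            mask_union([a, b])

    def test_empty_list(self):
        with pytest.raises(EmptyInputError):
            mask_union([])

    @settings(max_examples=25, deadline=None)
    @given(a=bool_grids, b=bool_grids, c=bool_grids)
    def test_idempotent_commutative_associative(self, a, b, c):
        ma, mb, mc = mask_of(a), mask_of(b), mask_of(c)
        assert np.array_equal(mask_union([ma, ma]).grid, a)
        assert np.array_equal(mask_union([ma, mb]).grid, mask_union([mb, ma]).grid)
        left = mask_union([mask_union([ma, mb]), mc]).grid
        right = mask_union([ma, mask_union([mb, mc])]).grid
        assert np.array_equal(left, right)


class TestMaskToMesh:
    def test_cube_volume(self, cube_mask):
        mesh = mask_to_mesh(cube_mask)
        assert mesh.is_closed()
        assert mesh.volume() == pytest.approx(1.0, rel=0.05)

    def test_sphere_volume(self):
        # rasterize an analytic r=1 cm sphere, then extract its surface
        n = 24
        c = (np.arange(n) + 0.5) * 0.1 - 1.2
        x, y, z = np.meshgrid(c, c, c, indexing="ij")
        grid = x**2 + y**2 + z**2 <= 1.0
        mesh = mask_to_mesh(BinaryMask(grid, (0.1, 0.1, 0.1)))
        assert mesh.volume() == pytest.approx(4.0 * np.pi / 3.0, rel=0.05)

    def test_single_voxel(self):
        g = np.zeros((3, 3, 3), bool)
        g[1, 1, 1] = True
        mesh = mask_to_mesh(BinaryMask(g, (0.1, 0.1, 0.1)))
        assert mesh.is_closed()
        assert mesh.volume() > 0

    def test_empty_mask(self):
        with pytest.raises(EmptyInputError):
            mask_to_mesh(BinaryMask(np.zeros((3, 3, 3), bool), (0.1, 0.1, 0.1)))

    def test_two_components(self):
        g = np.zeros((5, 5, 5), bool)
        g[0, 0, 0] = True
        g[4, 4, 4] = True
        with pytest.raises(ComponentError, match="2"):
            mask_to_mesh(BinaryMask(g, (0.1, 0.1, 0.1)))


class TestMeshToMask:
    def test_unit_cube_voxel_count(self, cube_mesh):
        mask = mesh_to_mask(cube_mesh, (0.1, 0.1, 0.1))
        assert np.count_nonzero(mask.grid) == pytest.approx(1000, abs=50)

    def test_valid_mesh_never_empty(self, sphere_mesh):
        mask = mesh_to_mask(sphere_mesh, (0.3, 0.3, 0.3))
        assert mask.grid.any()

    def test_refinement_consistency(self):
        sphere = generate_heart(
            HeartPhantomParams(semi_axes=(2.0, 2.0, 2.0), subdivisions=4)
        )
        v_coarse = mesh_to_mask(sphere, (0.2, 0.2, 0.2)).volume
        v_fine = mesh_to_mask(sphere, (0.1, 0.1, 0.1)).volume
        assert v_coarse == pytest.approx(v_fine, rel=0.03)

    def test_open_mesh_rejected(self, cube_mesh):
        open_mesh = SurfaceMesh(cube_mesh.vertices, cube_mesh.triangles[:-1])
        from heartnc.errors import TopologyError

        with pytest.raises(TopologyError):
            mesh_to_mask(open_mesh, (0.1, 0.1, 0.1))

    def test_roundtrip_jaccard(self, cube_mask):
        mesh = mask_to_mesh(cube_mask)
        back = voxelize_on_grid(
            mesh, cube_mask.grid.shape, cube_mask.spacing, cube_mask.origin
        )
        inter = np.count_nonzero(back.grid & cube_mask.grid)
        union = np.count_nonzero(back.grid | cube_mask.grid)
        assert inter / union >= 0.9

    @pytest.mark.parametrize(
        "mesh,analytic",
        [
            (make_cube_mesh(side=1.0), 1.0),
            (make_cube_mesh(side=1.6), 1.6**3),
            (generate_heart(HeartPhantomParams(semi_axes=(1.0, 1.0, 1.0))), 4.18879),
            (generate_heart(HeartPhantomParams(semi_axes=(1.5, 1.5, 1.5))), 14.137),
            (
                generate_heart(HeartPhantomParams(semi_axes=(1.0, 1.5, 2.0))),
                4.18879 * 1.5 * 2.0,
            ),
            (
                generate_heart(HeartPhantomParams(semi_axes=(2.0, 1.2, 1.0))),
                4.18879 * 2.0 * 1.2,
            ),
        ],
    )
    def test_volume_vs_analytic(self, mesh, analytic):
        assert mesh_to_mask(mesh, (0.1, 0.1, 0.1)).volume == pytest.approx(
            analytic, rel=0.05
        )


class TestAlignmentAndFields:
    def test_pure_offset(self, sphere_mesh):
        moving = sphere_mesh.translated((1.0, 2.0, 3.0))
        translation, moved = center_of_mass_align(moving, sphere_mesh)
        assert translation == pytest.approx([-1.0, -2.0, -3.0], abs=1e-12)
        assert np.allclose(moved.vertices, sphere_mesh.vertices)

    def test_identity(self, sphere_mesh):
        translation, _ = center_of_mass_align(sphere_mesh, sphere_mesh)
        assert translation == pytest.approx([0.0, 0.0, 0.0], abs=1e-15)

    def test_random_pair_centroids(self, rng, sphere_mesh, cube_mesh):
        _, moved = center_of_mass_align(sphere_mesh, cube_mesh)
        assert np.linalg.norm(moved.centroid() - cube_mesh.centroid()) < 1e-9

    def test_distances_preserved(self, rng, sphere_mesh, cube_mesh):
        _, moved = center_of_mass_align(sphere_mesh, cube_mesh)
        orig = np.linalg.norm(
            sphere_mesh.vertices[:50, None] - sphere_mesh.vertices[None, :50], axis=-1
        )
        new = np.linalg.norm(
            moved.vertices[:50, None] - moved.vertices[None, :50], axis=-1
        )
        assert np.abs(orig - new).max() < 1e-9

    def test_apply_zero_field(self, sphere_mesh):
        f = DeformationField(np.zeros((sphere_mesh.n_vertices, 3)))
        out = apply_field(sphere_mesh, f)
        assert np.array_equal(out.vertices, sphere_mesh.vertices)

    def test_apply_constant_field(self, sphere_mesh):
        f = DeformationField(np.tile([0.0, 0.0, 1.0], (sphere_mesh.n_vertices, 1)))
        out = apply_field(sphere_mesh, f)
        assert out.centroid() - sphere_mesh.centroid() == pytest.approx(
            [0.0, 0.0, 1.0], abs=1e-12
        )

    def test_apply_random_field_oracle(self, rng, sphere_mesh):
        d = rng.normal(size=(sphere_mesh.n_vertices, 3))
        out = apply_field(sphere_mesh, DeformationField(d))
        assert np.array_equal(out.vertices, sphere_mesh.vertices + d)

    def test_apply_inverse_roundtrip(self, rng, sphere_mesh):
        f = DeformationField(rng.normal(size=(sphere_mesh.n_vertices, 3)))
        there = apply_field(sphere_mesh, f)
        back = apply_field(there, -f)
        assert np.abs(back.vertices - sphere_mesh.vertices).max() < 1e-12

    def test_length_mismatch(self, sphere_mesh):
        with pytest.raises(IndexAlignmentError):
            apply_field(sphere_mesh, DeformationField(np.zeros((3, 3))))
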