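"""Voxel-grid and mesh primitives shared by all pipeline stages.

World coordinates follow a fixed patient frame (:data:`PATIENT_FRAME`):
+x is patient left, +y patient inferior, +z patient posterior, units cm.
Voxel ``(i, j, k)`` of a grid with spacing ``(sx, sy, sz)`` and origin ``o``
has its *center* at ``o + (i + 1/2, j + 1/2, k + 1/2) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .errors import (
    ComponentError,
    EmptyInputError,
    GridMismatchError,
    IndexAlignmentError,
    TopologyError,
)

__all__ = [
    "PATIENT_FRAME",
    "PatientFrame",
    "BinaryMask",
    "SurfaceMesh",
    "DeformationField",
    "mask_union",
    "mask_to_mesh",
    "mesh_to_mask",
    "voxelize_on_grid",
    "center_of_mass_align",
    "apply_field",
]


@dataclass(frozen=True)
class PatientFrame:
    """Axis convention for every world coordinate in the package."""

    x_axis: str = "patient-left"
    y_axis: str = "patient-inferior"
    z_axis: str = "patient-posterior"
    units: str = "cm"


PATIENT_FRAME = PatientFrame()

#: CT-style default voxel spacing in cm.
DEFAULT_SPACING = (0.1, 0.1, 0.3)


def _as_spacing(spacing):
    s = np.asarray(spacing, dtype=float)
    if s.shape != (3,) or not np.all(s > 0):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing!r}")
    return tuple(s)


@dataclass
class BinaryMask:
    """3D boolean voxel grid with physical spacing (cm)."""

    grid: np.ndarray
    spacing: tuple = DEFAULT_SPACING
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise EmptyInputError("mask grid must be a non-empty 3D array")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def volume(self) -> float:
        """Enclosed volume in cm^3 (true-voxel count times voxel volume)."""
        return float(np.count_nonzero(self.grid)) * self.voxel_volume

    def same_grid(self, other: "BinaryMask") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def voxel_centers_1d(self, axis: int) -> np.ndarray:
        n = self.grid.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def center_of_mass(self) -> np.ndarray:
        if not self.grid.any():
            raise EmptyInputError("center of mass of an all-false mask")
        idx = np.argwhere(self.grid)
        com_idx = idx.mean(axis=0) + 0.5
        return np.asarray(self.origin) + com_idx * np.asarray(self.spacing)


@dataclass
class SurfaceMesh:
    """Closed triangulated surface; vertices in world cm."""

    vertices: np.ndarray
    triangles: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise TopologyError("vertices must be an (N, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise TopologyError("triangles must be an (M, 3) array")
        if len(self.triangles) == 0:
            raise TopologyError("mesh has no triangles")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def centroid(self) -> np.ndarray:
        """Plain vertex average (the 'center of mass' used for rigid alignment)."""
        return self.vertices.mean(axis=0)

    def triangle_corners(self):
        v = self.vertices
        t = self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def signed_volume(self) -> float:
        a, b, c = self.triangle_corners()
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def volume(self) -> float:
        return abs(self.signed_volume())

    def is_closed(self) -> bool:
        """True iff every directed edge appears exactly once (closed, consistently oriented)."""
        t = self.triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        fwd = {tuple(e) for e in edges.tolist()}
        if len(fwd) != len(edges):
            return False
        return all((b, a) in fwd for a, b in fwd)

    def require_closed(self, what: str = "mesh"):
        if not self.is_closed():
            raise TopologyError(f"{what} is not a closed, consistently oriented surface")

    def bbox(self):
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def vertex_adjacency(self):
        """List of neighbor-index arrays per vertex."""
        nbrs = [set() for _ in range(self.n_vertices)]
        for a, b, c in self.triangles:
            nbrs[a].update((b, c))
            nbrs[b].update((a, c))
            nbrs[c].update((a, b))
        return [np.fromiter(s, dtype=np.int64) for s in nbrs]

    def translated(self, t) -> "SurfaceMesh":
        return replace(self, vertices=self.vertices + np.asarray(t, dtype=float))


@dataclass
class DeformationField:
    """Per-vertex 3D displacements (cm), index-aligned with a source mesh."""

    displacements: np.ndarray
    source_mesh: str = ""

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 2 or self.displacements.shape[1] != 3:
            raise IndexAlignmentError("displacements must be an (N, 3) array")
        if not np.all(np.isfinite(self.displacements)):
            raise IndexAlignmentError("displacements must be finite")

    def __len__(self):
        return len(self.displacements)

    def __neg__(self):
        return DeformationField(-self.displacements, self.source_mesh)


# ---------------------------------------------------------------------------
# operations


def mask_union(masks) -> BinaryMask:
    """Elementwise logical OR of masks sharing one grid."""
    masks = list(masks)
    if not masks:
        raise EmptyInputError("mask_union needs at least one mask")
    first = masks[0]
    out = first.grid.copy()
    for i, m in enumerate(masks[1:], start=1):
        if not first.same_grid(m):
            raise GridMismatchError(
                f"mask {i} grid (shape {m.grid.shape}, spacing {m.spacing}, "
                f"origin {m.origin}) differs from mask 0"
            )
        out |= m.grid
    return BinaryMask(out, first.spacing, first.origin)


def _laplacian_smooth(vertices, adjacency, iters, lam=0.5, mu=-0.53):
    """Taubin smoothing (shrink-limited)."""
    v = vertices.copy()
    for _ in range(iters):
        for f in (lam, mu):
            mean = np.empty_like(v)
            for i, nb in enumerate(adjacency):
                mean[i] = v[nb].mean(axis=0)
            v += f * (mean - v)
    return v


def mask_to_mesh(mask: BinaryMask, smoothing_iters: int = 0) -> SurfaceMesh:
    """Extract a closed triangulated surface from a single-component mask.

    Marching cubes on the zero-padded grid, so the surface is always
    watertight; vertices are placed at the 0.5 iso-level between voxel
    centers, giving enclosed volumes within a half-voxel shell of the
    voxel-count volume.
    """
    if not mask.grid.any():
        raise EmptyInputError("mask_to_mesh: mask has no true voxels")
    _, n_comp = ndimage.label(mask.grid)
    if n_comp > 1:
        raise ComponentError(
            f"mask_to_mesh: mask has {n_comp} connected components, expected 1"
        )
    padded = np.pad(mask.grid, 1).astype(np.float32)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    # padded index -> unpadded index -> voxel-center world coordinate
    spacing = np.asarray(mask.spacing)
    world = np.asarray(mask.origin) + (verts - 1.0 + 0.5) * spacing
    mesh = SurfaceMesh(world, faces)
    if mesh.signed_volume() < 0:
        mesh = SurfaceMesh(world, faces[:, ::-1])
    if smoothing_iters > 0:
        adj = mesh.vertex_adjacency()
        mesh = SurfaceMesh(
            _laplacian_smooth(mesh.vertices, adj, smoothing_iters), mesh.triangles
        )
    mesh.require_closed("extracted surface")
    return mesh


def _ray_crossings(mesh: SurfaceMesh, y_centers, z_centers, perturb):
    """X-coordinates where +x rays through the (y, z) center lattice cross the surface.

    Returns dict mapping flat ray index (j * nz + k) -> sorted list of x crossings.
    Rays are offset by a deterministic sub-voxel perturbation so that edge
    grazing is measure-zero.
    """
    ys = np.asarray(y_centers) + perturb[0]
    zs = np.asarray(z_centers) + perturb[1]
    nz = len(zs)
    a, b, c = mesh.triangle_corners()
    crossings: dict[int, list[float]] = {}
    for ta, tb, tc in zip(a, b, c):
        ymin, ymax = min(ta[1], tb[1], tc[1]), max(ta[1], tb[1], tc[1])
        zmin, zmax = min(ta[2], tb[2], tc[2]), max(ta[2], tb[2], tc[2])
        j0, j1 = np.searchsorted(ys, [ymin, ymax])
        k0, k1 = np.searchsorted(zs, [zmin, zmax])
        if j0 == j1 or k0 == k1:
            continue
        # 2D barycentric solve in the (y, z) projection
        d1 = (tb[1] - ta[1], tb[2] - ta[2])
        d2 = (tc[1] - ta[1], tc[2] - ta[2])
        det = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(det) < 1e-14:
            continue  # triangle (nearly) parallel to the ray direction
        yy, zz = np.meshgrid(ys[j0:j1], zs[k0:k1], indexing="ij")
        py, pz = yy - ta[1], zz - ta[2]
        u = (py * d2[1] - pz * d2[0]) / det
        v = (pz * d1[0] - py * d1[1]) / det
        hit = (u >= 0) & (v >= 0) & (u + v <= 1)
        if not hit.any():
            continue
        xhit = ta[0] + u * (tb[0] - ta[0]) + v * (tc[0] - ta[0])
        jj, kk = np.nonzero(hit)
        for j, k, x in zip(jj + j0, kk + k0, xhit[hit]):
            crossings.setdefault(int(j) * nz + int(k), []).append(float(x))
    return crossings


def voxelize_on_grid(mesh: SurfaceMesh, shape, spacing, origin) -> BinaryMask:
    """Rasterize a closed mesh onto an explicit grid (voxel-center parity rule)."""
    mesh.require_closed("voxelization input")
    spacing = _as_spacing(spacing)
    origin = tuple(float(v) for v in origin)
    nx, ny, nz = shape
    xs = origin[0] + (np.arange(nx) + 0.5) * spacing[0]
    ys = origin[1] + (np.arange(ny) + 0.5) * spacing[1]
    zs = origin[2] + (np.arange(nz) + 0.5) * spacing[2]
    # distinct irrational-ratio offsets so rays can graze neither axis-aligned
    # nor diagonal triangulation edges
    perturb = (0.41421356e-3 * spacing[1], 0.73205081e-3 * spacing[2])
    crossings = _ray_crossings(mesh, ys, zs, perturb)
    grid = np.zeros(shape, dtype=bool)
    for flat, xlist in crossings.items():
        j, k = divmod(flat, nz)
        xlist.sort()
        n_pairs = len(xlist) // 2
        for p in range(n_pairs):
            i0 = np.searchsorted(xs, xlist[2 * p], side="left")
            i1 = np.searchsorted(xs, xlist[2 * p + 1], side="left")
            grid[i0:i1, j, k] = True
    return BinaryMask(grid, spacing, origin)


def mesh_to_mask(mesh: SurfaceMesh, spacing=(0.1, 0.1, 0.1), padding: float = 0.5) -> BinaryMask:
    """Voxelize a closed mesh on a grid derived from its bounding box."""
    spacing = _as_spacing(spacing)
    lo, hi = mesh.bbox()
    origin = lo - padding
    extent = hi + padding - origin
    shape = tuple(int(np.ceil(extent[d] / spacing[d])) for d in range(3))
    return voxelize_on_grid(mesh, shape, spacing, tuple(origin))


def center_of_mass_align(moving: SurfaceMesh, fixed: SurfaceMesh):
    """Rigidly translate ``moving`` so vertex centroids coincide.

    Returns ``(translation, moved)`` with ``moved = moving + translation``.
    """
    translation = fixed.centroid() - moving.centroid()
    return translation, moving.translated(translation)


def apply_field(mesh: SurfaceMesh, field: DeformationField) -> SurfaceMesh:
    """Displace every vertex by its field vector; connectivity unchanged."""
    if len(field) != mesh.n_vertices:
        raise IndexAlignmentError(
            f"field length {len(field)} != vertex count {mesh.n_vertices}"
        )
    return replace(mesh, vertices=mesh.vertices + field.displacements)
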