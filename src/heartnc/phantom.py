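"""Seeded synthetic hearts, thoraces and ground-truth deformations.

Every generator is a pure function of its parameter record, so downstream
stages can be tested against known ground truth without patient data.

The heart is an ellipsoid plus four Gaussian radial bulges at the lateral
chamber positions (right/left x upper/lower), which gives the silhouette
the curvature structure that the four horizontal navigator channels exist
to capture.  The thorax is an elliptical soft-tissue cylinder with a
posterior spine column and two rib bands whose inner borders realize the
requested W1/W2 gaps exactly; attenuation is a unitless relative scale
(air 0, soft tissue 1, heart 1.5, bone 3 by default) because edge contrast,
not dosimetry, is what the projection stage needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError
from .geometry_core import (
    BinaryMask,
    DeformationField,
    SurfaceMesh,
    voxelize_on_grid,
)
from .projection import CTVolume

__all__ = [
    "HeartPhantomParams",
    "ThoraxPhantomParams",
    "DeformationSpec",
    "ThoraxLayout",
    "generate_heart",
    "generate_thorax_ct",
    "generate_deformed_pair",
    "thorax_layout",
    "thorax_grid",
    "icosphere",
]


# ---------------------------------------------------------------------------
# parameter records


@dataclass(frozen=True)
class HeartPhantomParams:
    """Base ellipsoid semi-axes (cm), four lateral bulge amplitudes (cm),
    center (cm), bulge angular width (radians) and subdivision level."""

    semi_axes: tuple = (4.5, 5.5, 4.0)
    lobe_amplitudes: tuple = (0.0, 0.0, 0.0, 0.0)
    center: tuple = (0.0, 0.0, 0.0)
    lobe_sigma: float = 0.55
    exponent: float = 2.0  # superellipsoid exponent; 2 = ellipsoid, higher = boxier
    subdivisions: int = 3
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.semi_axes) != 3 or any(a <= 0 for a in self.semi_axes):
            raise ParameterError(f"semi_axes must be 3 positive floats, got {self.semi_axes}")
        if len(self.lobe_amplitudes) != 4 or any(a < 0 for a in self.lobe_amplitudes):
            raise ParameterError("lobe_amplitudes must be 4 non-negative floats")
        if self.jitter < 0:
            raise ParameterError("jitter must be >= 0")
        if self.exponent < 2.0:
            raise ParameterError("exponent must be >= 2")


@dataclass(frozen=True)
class ThoraxPhantomParams:
    """Thorax measurements (cm) plus relative attenuations and grid layout."""

    W1: float = 15.0
    W2: float = 24.8
    L: float = 14.3
    rib_attenuation: float = 3.0
    soft_tissue_attenuation: float = 1.0
    heart_attenuation: float = 1.5
    group_label: str = "M"
    spacing: tuple = (0.1, 0.1, 0.3)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.W1, self.W2, self.L) <= 0:
            raise ParameterError("W1, W2 and L must be positive")
        if min(self.rib_attenuation, self.soft_tissue_attenuation, self.heart_attenuation) < 0:
            raise ParameterError("attenuations must be non-negative")


@dataclass(frozen=True)
class DeformationSpec:
    """Smooth bijective map applied to mesh vertices.

    kinds: ``translate`` (offset: 3-vector), ``scale`` (factors: scalar or
    3-vector, about the mesh centroid), ``bend`` (amplitude cm: lateral
    x-offset varying quadratically with y), ``composite`` (parts applied in
    order).
    """

    kind: str = "translate"
    offset: tuple = (0.0, 0.0, 0.0)
    factors: tuple | float = 1.0
    amplitude: float = 0.0
    parts: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("translate", "scale", "bend", "composite", "identity"):
            raise ParameterError(f"unknown deformation kind {self.kind!r}")
        f = np.atleast_1d(np.asarray(self.factors, dtype=float))
        if self.kind == "scale" and np.any(f <= 0):
            raise ParameterError("scale factors must be positive (bijectivity)")


@dataclass(frozen=True)
class ThoraxLayout:
    """Derived deterministic geometry of a thorax phantom (all cm)."""

    upper_row_y: float
    lower_row_y: float
    x_half: float
    y_extent: float
    z_half: float
    landmarks: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# icosphere


def icosphere(subdivisions: int = 3):
    """Unit icosphere: (vertices, triangles); 642 vertices at level 3."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = np.asarray(verts[a]) + np.asarray(verts[b])
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=np.int64)


# Bulge directions in the radiograph plane; +x patient left, +y inferior.
# Order matches the lateral channel roles: NC1 right-lower, NC2 left-lower,
# NC3 right-upper, NC4 left-upper.
_LOBE_ANGLE = np.deg2rad(35.0)
LOBE_DIRECTIONS = np.array(
    [
        (-np.cos(_LOBE_ANGLE), np.sin(_LOBE_ANGLE), 0.0),
        (np.cos(_LOBE_ANGLE), np.sin(_LOBE_ANGLE), 0.0),
        (-np.cos(_LOBE_ANGLE), -np.sin(_LOBE_ANGLE), 0.0),
        (np.cos(_LOBE_ANGLE), -np.sin(_LOBE_ANGLE), 0.0),
    ]
)


def generate_heart(params: HeartPhantomParams) -> SurfaceMesh:
    """Closed heart surface: radial ellipsoid distance plus Gaussian bulges."""
    a, b, c = params.semi_axes
    p = params.exponent
    dirs, faces = icosphere(params.subdivisions)
    norm = (
        np.abs(dirs[:, 0] / a) ** p
        + np.abs(dirs[:, 1] / b) ** p
        + np.abs(dirs[:, 2] / c) ** p
    )
    radius = norm ** (-1.0 / p)
    for amp, d in zip(params.lobe_amplitudes, LOBE_DIRECTIONS):
        if amp > 0:
            ang = np.arccos(np.clip(dirs @ d, -1.0, 1.0))
            radius = radius + amp * np.exp(-0.5 * (ang / params.lobe_sigma) ** 2)
    if params.jitter > 0:
        rng = np.random.default_rng(params.seed)
        radius = radius + params.jitter * rng.standard_normal(len(radius))
    verts = np.asarray(params.center) + radius[:, None] * dirs
    mesh = SurfaceMesh(verts, faces, name="heart-phantom")
    if mesh.signed_volume() < 0:
        mesh = SurfaceMesh(verts, faces[:, ::-1], name="heart-phantom")
    return mesh


# ---------------------------------------------------------------------------
# thorax CT

RIB_BAND_HALF_HEIGHT = 0.5  # cm
RIB_DEPTH = 2.0  # lateral bone margin beyond the inner border, cm
Y_MARGIN = 5.0  # grid margin above the upper / below the lower rib row, cm


def thorax_layout(params: ThoraxPhantomParams) -> ThoraxLayout:
    upper = Y_MARGIN
    lower = Y_MARGIN + params.L
    x_half = max(params.W1, params.W2) / 2.0 + RIB_DEPTH + 1.0
    z_half = 0.65 * x_half + 1.0
    landmarks = {
        "sternal_notch": (0.0, upper + 2.0),
        "spinous_T6": (0.0, upper + 0.45 * params.L),
        "spinous_T8": (0.0, upper + 0.70 * params.L),
    }
    return ThoraxLayout(
        upper_row_y=upper,
        lower_row_y=lower,
        x_half=x_half,
        y_extent=params.L + 2 * Y_MARGIN,
        z_half=z_half,
        landmarks=landmarks,
    )


def thorax_grid(params: ThoraxPhantomParams):
    """(shape, spacing, origin) of the CT grid a thorax phantom will occupy."""
    lay = thorax_layout(params)
    sx, sy, sz = params.spacing
    shape = (
        int(np.ceil(2 * lay.x_half / sx)),
        int(np.ceil(lay.y_extent / sy)),
        int(np.ceil(2 * lay.z_half / sz)),
    )
    return shape, params.spacing, (-lay.x_half, 0.0, -lay.z_half)


def generate_thorax_ct(
    thorax: ThoraxPhantomParams,
    heart: SurfaceMesh,
    heart_mask: BinaryMask | None = None,
) -> CTVolume:
    """Synthesize a relative-attenuation CT holding the given heart.

    The body is an elliptical cylinder whose lateral semi-axis interpolates
    between the two rib rows; bone rib bands occupy an outer annulus
    restricted to ``|x| >= W/2`` so the projected inner rib border sits at
    exactly +-W/2 on each row.  A posterior spine column runs the full
    length.  The heart overwrites soft tissue only.
    """
    lay = thorax_layout(thorax)
    sx, sy, sz = thorax.spacing
    nx = int(np.ceil(2 * lay.x_half / sx))
    ny = int(np.ceil(lay.y_extent / sy))
    nz = int(np.ceil(2 * lay.z_half / sz))
    origin = (-lay.x_half, 0.0, -lay.z_half)

    xs = origin[0] + (np.arange(nx) + 0.5) * sx
    ys = origin[1] + (np.arange(ny) + 0.5) * sy
    zs = origin[2] + (np.arange(nz) + 0.5) * sz

    # lateral semi-axis per y: linear between rows, clamped outside
    sa1 = thorax.W1 / 2.0 + RIB_DEPTH
    sa2 = thorax.W2 / 2.0 + RIB_DEPTH
    t = np.clip((ys - lay.upper_row_y) / (lay.lower_row_y - lay.upper_row_y), 0.0, 1.0)
    semi_x = sa1 + (sa2 - sa1) * t  # (ny,)
    # constant AP thickness: a y-varying chord would superimpose background
    # gradients on the vertical channel profiles
    semi_z = np.full_like(semi_x, 0.65 * max(sa1, sa2))

    x2 = xs[:, None] ** 2  # (nx, 1)
    z2 = zs[None, :] ** 2  # (1, nz)
    grid = np.zeros((nx, ny, nz), dtype=np.float32)
    frac2 = (
        x2[:, None, :] / semi_x[None, :, None] ** 2
        + z2[None, :, :] / semi_z[None, :, None] ** 2
    )  # (nx, ny, nz)
    body = frac2 <= 1.0
    grid[body] = thorax.soft_tissue_attenuation

    # rib bands: outer annulus of the local ellipse, outside the inner border
    for row_y, w in ((lay.upper_row_y, thorax.W1), (lay.lower_row_y, thorax.W2)):
        band = np.abs(ys - row_y) <= RIB_BAND_HALF_HEIGHT
        annulus = (frac2[:, band, :] >= 0.82**2) & (frac2[:, band, :] <= 1.0)
        lateral = (np.abs(xs) >= w / 2.0)[:, None, None]
        sub = grid[:, band, :]
        sub[annulus & lateral] = thorax.rib_attenuation
        grid[:, band, :] = sub

    # spine: posterior midline column
    spine = (
        (np.abs(xs) <= 1.2)[:, None, None]
        & body
        & (zs >= 0.35 * semi_z[:, None])[None, :, :]
    )
    grid[spine] = thorax.rib_attenuation

    # heart
    if heart_mask is None:
        heart_mask = voxelize_on_grid(heart, (nx, ny, nz), thorax.spacing, origin)
    elif heart_mask.grid.shape != (nx, ny, nz):
        raise GeometryError("supplied heart_mask does not match the thorax grid")
    lo, hi = heart.bbox()
    for vy, vx, vzc in ((lo[1], lo[0], lo[2]), (hi[1], hi[0], hi[2])):
        i = int(np.clip(np.searchsorted(ys, vy), 0, ny - 1))
        if (vx / semi_x[i]) ** 2 + (vzc / semi_z[i]) ** 2 > 0.95**2:
            raise GeometryError(
                "heart does not fit inside the thorax ellipse with margin"
            )
    soft = np.isclose(grid, thorax.soft_tissue_attenuation)
    grid[heart_mask.grid & soft] = thorax.heart_attenuation

    if thorax.noise_sigma > 0:
        rng = np.random.default_rng(thorax.seed)
        grid = grid + thorax.noise_sigma * rng.standard_normal(grid.shape).astype(np.float32)

    return CTVolume(grid, thorax.spacing, origin)


# ---------------------------------------------------------------------------
# ground-truth deformations


def _apply_spec(spec: DeformationSpec, verts: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    if spec.kind == "identity":
        return verts.copy()
    if spec.kind == "translate":
        return verts + np.asarray(spec.offset, dtype=float)
    if spec.kind == "scale":
        f = np.broadcast_to(np.atleast_1d(np.asarray(spec.factors, dtype=float)), (3,))
        return centroid + (verts - centroid) * f
    if spec.kind == "bend":
        lo, hi = verts[:, 1].min(), verts[:, 1].max()
        half = max((hi - lo) / 2.0, 1e-9)
        mid = (hi + lo) / 2.0
        u = (verts[:, 1] - mid) / half
        out = verts.copy()
        out[:, 0] = out[:, 0] + spec.amplitude * u**2
        return out
    # composite
    out = verts
    for part in spec.parts:
        out = _apply_spec(part, out, centroid)
    return out


def generate_deformed_pair(heart_params: HeartPhantomParams, spec: DeformationSpec):
    """(reference mesh, test mesh, exact reference->test displacement field)."""
    reference = generate_heart(heart_params)
    test_verts = _apply_spec(spec, reference.vertices, reference.centroid())
    test = SurfaceMesh(test_verts, reference.triangles.copy(), name="heart-phantom-test")
    true_field = DeformationField(test_verts - reference.vertices)
    return reference, test, true_field
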