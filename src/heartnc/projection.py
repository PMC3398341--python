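"""Anterior radiograph synthesis and 2D image normalization.

A radiograph is produced by parallel projection of a CT attenuation volume
along +z (anterior-posterior): both images of a pair are normalized to the
same magnification before any measurement, so only relative geometry
matters and divergent ray casting would add an untestable free parameter.
The source-to-axis distance is kept as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.measure import find_contours

from .errors import AnnotationError, CalibrationError, EmptyInputError
from .geometry_core import BinaryMask, _as_spacing

__all__ = ["CTVolume", "DRRImage", "Rigid2D", "render_drr", "scale_to_reference", "rigid_align_2d"]

#: landmark names used for rigid pair alignment (mid sternal notch and two
#: mid spinous processes along the midline).
ALIGNMENT_LANDMARKS = ("sternal_notch", "spinous_T6", "spinous_T8")


@dataclass
class CTVolume:
    """3D relative-attenuation volume; axes (x, y, z), spacing in cm."""

    grid: np.ndarray
    spacing: tuple = (0.1, 0.1, 0.3)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise EmptyInputError("CT grid must be a non-empty 3D array")
        if not np.all(np.isfinite(self.grid)):
            raise EmptyInputError("CT grid must be finite")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)


@dataclass
class DRRImage:
    """2D projected radiograph. ``pixels[row, col]``: row = y (inferior), col = x (left).

    ``origin`` is the world (x, y) of the corner of pixel (0, 0); pixel
    centers sit at ``origin + (col + 1/2, row + 1/2) * pixel_spacing``.
    """

    pixels: np.ndarray
    pixel_spacing: tuple
    origin: tuple = (0.0, 0.0)
    isocenter_px: tuple | None = None
    heart_contour: np.ndarray | None = None
    landmarks: dict | None = None
    sad_cm: float = 100.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise EmptyInputError("DRR pixels must be 2D")
        px, py = self.pixel_spacing
        if px <= 0 or py <= 0:
            raise EmptyInputError("pixel spacing must be positive")
        self.pixel_spacing = (float(px), float(py))
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if self.landmarks is None:
            self.landmarks = {}

    @property
    def shape(self):
        return self.pixels.shape

    def x_of_col(self, col):
        return self.origin[0] + (np.asarray(col) + 0.5) * self.pixel_spacing[0]

    def y_of_row(self, row):
        return self.origin[1] + (np.asarray(row) + 0.5) * self.pixel_spacing[1]

    def col_of_x(self, x):
        return (np.asarray(x) - self.origin[0]) / self.pixel_spacing[0] - 0.5

    def row_of_y(self, y):
        return (np.asarray(y) - self.origin[1]) / self.pixel_spacing[1] - 0.5


@dataclass
class Rigid2D:
    """Translation-only 2D rigid transform (cm).

    Rotation is fixed at zero: the three alignment landmarks are nearly
    collinear along the midline, which makes a fitted rotation
    ill-conditioned.
    """

    translation: tuple

    def apply(self, points):
        return np.asarray(points, dtype=float) + np.asarray(self.translation)


def silhouette_contour(mask: BinaryMask) -> np.ndarray:
    """Closed 2D outline (world cm, (x, y) columns) of a mask's z-projection."""
    proj = mask.grid.any(axis=2)  # (nx, ny)
    if not proj.any():
        raise EmptyInputError("silhouette of an empty mask")
    contours = find_contours(proj.astype(float), 0.5)
    longest = max(contours, key=len)  # rows are x-index, cols are y-index
    x = mask.origin[0] + (longest[:, 0] + 0.5) * mask.spacing[0]
    y = mask.origin[1] + (longest[:, 1] + 0.5) * mask.spacing[1]
    return np.column_stack([x, y])


def render_drr(ct: CTVolume, heart_mask: BinaryMask | None = None,
               isocenter_px=None, landmarks=None) -> DRRImage:
    """Parallel projection along z: ``pixel(r, c) = sum_k grid[c, r, k] * sz``."""
    sz = ct.spacing[2]
    pixels = ct.grid.sum(axis=2).T * sz  # (rows=y, cols=x)
    contour = silhouette_contour(heart_mask) if heart_mask is not None else None
    return DRRImage(
        pixels=pixels,
        pixel_spacing=(ct.spacing[0], ct.spacing[1]),
        origin=(ct.origin[0], ct.origin[1]),
        isocenter_px=isocenter_px,
        heart_contour=contour,
        landmarks=dict(landmarks) if landmarks else {},
    )


def scale_to_reference(test: DRRImage, ref: DRRImage, ref_pts, test_pts) -> DRRImage:
    """Rescale the test image's physical calibration to reference magnification.

    ``ref_pts`` / ``test_pts`` are two graticule points (cm) on each image;
    the test pixel spacing is multiplied by ``s = dist(ref) / dist(test)``.
    Pixel content is untouched; all physical annotations are rescaled with
    the calibration.
    """
    ref_pts = np.asarray(ref_pts, dtype=float)
    test_pts = np.asarray(test_pts, dtype=float)
    d_ref = float(np.linalg.norm(ref_pts[1] - ref_pts[0]))
    d_test = float(np.linalg.norm(test_pts[1] - test_pts[0]))
    min_sep = min(test.pixel_spacing)
    if d_ref <= min_sep or d_test <= min_sep:
        raise CalibrationError(
            f"graticule points coincide (ref separation {d_ref:.3g} cm, "
            f"test {d_test:.3g} cm)"
        )
    s = d_ref / d_test
    return replace(
        test,
        pixel_spacing=(test.pixel_spacing[0] * s, test.pixel_spacing[1] * s),
        origin=(test.origin[0] * s, test.origin[1] * s),
        landmarks={k: (v[0] * s, v[1] * s) for k, v in test.landmarks.items()},
        heart_contour=None if test.heart_contour is None else test.heart_contour * s,
    )


def rigid_align_2d(ref: DRRImage, test: DRRImage, landmark_names=ALIGNMENT_LANDMARKS) -> Rigid2D:
    """Translation minimizing summed squared landmark residuals (centroid difference)."""
    missing = [n for n in landmark_names if n not in ref.landmarks or n not in test.landmarks]
    if missing:
        raise AnnotationError(f"missing landmarks: {', '.join(missing)}", missing)
    ref_pts = np.asarray([ref.landmarks[n] for n in landmark_names], dtype=float)
    test_pts = np.asarray([test.landmarks[n] for n in landmark_names], dtype=float)
    t = ref_pts.mean(axis=0) - test_pts.mean(axis=0)
    return Rigid2D(translation=(float(t[0]), float(t[1])))


def apply_rigid(drr: DRRImage, transform: Rigid2D) -> DRRImage:
    """Shift a radiograph's physical frame by a translation (content untouched)."""
    tx, ty = transform.translation
    return replace(
        drr,
        origin=(drr.origin[0] + tx, drr.origin[1] + ty),
        landmarks={k: (v[0] + tx, v[1] + ty) for k, v in drr.landmarks.items()},
        heart_contour=None
        if drr.heart_contour is None
        else drr.heart_contour + np.asarray([tx, ty]),
    )
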