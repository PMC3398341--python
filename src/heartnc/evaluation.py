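"""Volume-overlap accuracy: Dice coefficient, cohort summaries and paired
comparison statistics.

Dice is computed on voxel counts, ``2|A^B| / (|A|+|B|) * 100``.  Meshes are
voxelized on a shared grid (0.2 cm isotropic by default -- the full CT grid
is available via ``spacing`` but costs 8x the voxels).  Center-of-mass
alignment defaults ON for reconstruction-vs-truth comparisons and should
be switched OFF for free-breathing inhale/exhale comparisons, where the
positional variation is part of the quantity being measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateTestError, EmptyInputError
from .geometry_core import BinaryMask, SurfaceMesh, voxelize_on_grid

__all__ = ["DiceResult", "CohortSummary", "dice", "paired_t", "summarize"]

DEFAULT_EVAL_SPACING = (0.2, 0.2, 0.2)


@dataclass(frozen=True)
class DiceResult:
    dice_pct: float
    volume1: float
    volume2: float
    intersection: float
    grid_spacing: tuple


@dataclass(frozen=True)
class CohortSummary:
    values: tuple
    avg: float
    min: float
    max: float
    sd: float


def _counts_dice(a_grid, b_grid, voxel_volume, spacing) -> DiceResult:
    n_a = int(np.count_nonzero(a_grid))
    n_b = int(np.count_nonzero(b_grid))
    if n_a == 0 and n_b == 0:
        raise EmptyInputError("Dice undefined: both volumes are empty")
    n_i = int(np.count_nonzero(a_grid & b_grid))
    return DiceResult(
        dice_pct=200.0 * n_i / (n_a + n_b),
        volume1=n_a * voxel_volume,
        volume2=n_b * voxel_volume,
        intersection=n_i * voxel_volume,
        grid_spacing=tuple(spacing),
    )


def _mask_pair_dice(a: BinaryMask, b: BinaryMask, com_align: bool) -> DiceResult:
    if not np.allclose(a.spacing, b.spacing):
        raise EmptyInputError("mask Dice requires identical spacing")
    # map b's voxel indices into a's index frame (rounded to whole voxels)
    t = a.center_of_mass() - b.center_of_mass() if com_align else np.zeros(3)
    shift_vox = np.round(
        (np.asarray(b.origin) + t - np.asarray(a.origin)) / np.asarray(b.spacing)
    ).astype(int)
    b_grid = np.zeros_like(a.grid)
    src = np.argwhere(b.grid) + shift_vox
    keep = np.all((src >= 0) & (src < np.asarray(a.grid.shape)), axis=1)
    src = src[keep]
    b_grid[src[:, 0], src[:, 1], src[:, 2]] = True
    return _counts_dice(a.grid, b_grid, a.voxel_volume, a.spacing)


def dice(a, b, com_align: bool = True, spacing=DEFAULT_EVAL_SPACING, padding: float = 1.0) -> DiceResult:
    """Percentage volume overlap of two masks or meshes.

    Meshes (in any combination with masks) are voxelized on a shared grid
    covering both, after optional rigid center-of-mass alignment of the
    second input onto the first.
    """
    if isinstance(a, BinaryMask) and isinstance(b, BinaryMask):
        return _mask_pair_dice(a, b, com_align)

    def as_mesh(obj):
        if isinstance(obj, SurfaceMesh):
            return obj
        raise EmptyInputError(f"dice: unsupported type {type(obj).__name__}")

    if isinstance(a, BinaryMask):
        mesh_b = as_mesh(b)
        if com_align:
            mesh_b = mesh_b.translated(a.center_of_mass() - mesh_b.centroid())
        mask_b = voxelize_on_grid(mesh_b, a.grid.shape, a.spacing, a.origin)
        return _counts_dice(a.grid, mask_b.grid, a.voxel_volume, a.spacing)
    if isinstance(b, BinaryMask):
        res = dice(b, a, com_align=com_align, spacing=spacing, padding=padding)
        return DiceResult(res.dice_pct, res.volume2, res.volume1,
                          res.intersection, res.grid_spacing)

    mesh_a, mesh_b = as_mesh(a), as_mesh(b)
    if com_align:
        mesh_b = mesh_b.translated(mesh_a.centroid() - mesh_b.centroid())
    lo = np.minimum(mesh_a.bbox()[0], mesh_b.bbox()[0]) - padding
    hi = np.maximum(mesh_a.bbox()[1], mesh_b.bbox()[1]) + padding
    spacing = tuple(float(s) for s in spacing)
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing[d])) for d in range(3))
    ga = voxelize_on_grid(mesh_a, shape, spacing, tuple(lo))
    gb = voxelize_on_grid(mesh_b, shape, spacing, tuple(lo))
    return _counts_dice(ga.grid, gb.grid, ga.voxel_volume, spacing)


def paired_t(a, b):
    """Student's paired t-test; returns (t, two-sided p).

    Identical samples give (0, 1); differences with zero variance but a
    nonzero mean are degenerate (t undefined) and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise EmptyInputError("paired_t needs two equal-length samples, n >= 2")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        raise DegenerateTestError(
            "differences have zero variance with nonzero mean: t is undefined"
        )
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def summarize(cohort) -> CohortSummary:
    """Average / min / max / sample-sd of a list of Dice results (or floats)."""
    values = [c.dice_pct if isinstance(c, DiceResult) else float(c) for c in cohort]
    if not values:
        raise EmptyInputError("summarize: empty cohort")
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return CohortSummary(
        values=tuple(values),
        avg=float(arr.mean()),
        min=float(arr.min()),
        max=float(arr.max()),
        sd=sd,
    )
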