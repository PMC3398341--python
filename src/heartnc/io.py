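"""File formats: NIfTI masks/volumes, VTK/PLY meshes, CSV deformation fields,
PNG + JSON-sidecar radiographs.

NIfTI headers are in mm; everything in-memory is cm, so spacing and origin
are divided/multiplied by 10 at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import TopologyError
from .geometry_core import BinaryMask, DeformationField, SurfaceMesh

MM_PER_CM = 10.0


# ---------------------------------------------------------------------------
# NIfTI


def _affine_cm(spacing, origin):
    aff = np.diag([spacing[0] * MM_PER_CM, spacing[1] * MM_PER_CM, spacing[2] * MM_PER_CM, 1.0])
    aff[:3, 3] = np.asarray(origin) * MM_PER_CM
    return aff


def write_mask_nifti(mask: BinaryMask, path):
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), _affine_cm(mask.spacing, mask.origin))
    nib.save(img, str(path))


def read_mask_nifti(path) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3] / MM_PER_CM
    return BinaryMask(data > 0, tuple(z / MM_PER_CM for z in zooms), tuple(origin))


def write_volume_nifti(grid, spacing, origin, path):
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), _affine_cm(spacing, origin))
    nib.save(img, str(path))


def read_volume_nifti(path):
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3] / MM_PER_CM
    return (
        np.asarray(img.dataobj, dtype=np.float32),
        tuple(z / MM_PER_CM for z in zooms),
        tuple(origin),
    )


# ---------------------------------------------------------------------------
# meshes


def write_mesh_vtk(mesh: SurfaceMesh, path, point_data: dict | None = None):
    """Legacy ASCII VTK PolyData, optionally with per-vertex vector data."""
    lines = [
        "# vtk DataFile Version 3.0",
        mesh.name or "surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{c:.10g}" for c in v) for v in mesh.vertices]
    m = len(mesh.triangles)
    lines.append(f"POLYGONS {m} {4 * m}")
    lines += ["3 " + " ".join(str(i) for i in t) for t in mesh.triangles]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f"VECTORS {name} double")
            lines += [" ".join(f"{c:.10g}" for c in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh_vtk(path):
    """Read legacy ASCII VTK PolyData written by :func:`write_mesh_vtk`.

    Returns ``(mesh, point_data)``.
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    verts = tris = None
    point_data = {}
    lines = [ln for ln in it]
    i = 0
    while i < len(lines):
        ln = lines[i].split()
        if not ln:
            i += 1
            continue
        if ln[0] == "POINTS":
            n = int(ln[1])
            flat = " ".join(lines[i + 1 : i + 1 + n]).split()
            verts = np.asarray(flat, dtype=float).reshape(n, 3)
            i += n + 1
        elif ln[0] == "POLYGONS":
            m = int(ln[1])
            rows = [lines[i + 1 + r].split() for r in range(m)]
            if any(r[0] != "3" for r in rows):
                raise TopologyError(f"{path}: non-triangular polygon in VTK file")
            tris = np.asarray([r[1:4] for r in rows], dtype=np.int64)
            i += m + 1
        elif ln[0] == "VECTORS":
            name = ln[1]
            n = len(verts)
            flat = " ".join(lines[i + 1 : i + 1 + n]).split()
            point_data[name] = np.asarray(flat, dtype=float).reshape(n, 3)
            i += n + 1
        else:
            i += 1
    if verts is None or tris is None:
        raise TopologyError(f"{path}: missing POINTS or POLYGONS section")
    return SurfaceMesh(verts, tris, name=Path(path).stem), point_data


def write_mesh_ply(mesh: SurfaceMesh, path):
    header = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(mesh.triangles)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    body = [" ".join(f"{c:.10g}" for c in v) for v in mesh.vertices]
    body += ["3 " + " ".join(str(i) for i in t) for t in mesh.triangles]
    Path(path).write_text("\n".join(header + body) + "\n")


def read_mesh_ply(path) -> SurfaceMesh:
    lines = Path(path).read_text().splitlines()
    n_v = n_f = None
    for i, ln in enumerate(lines):
        if ln.startswith("element vertex"):
            n_v = int(ln.split()[-1])
        elif ln.startswith("element face"):
            n_f = int(ln.split()[-1])
        elif ln.strip() == "end_header":
            start = i + 1
            break
    else:
        raise TopologyError(f"{path}: no PLY header terminator")
    verts = np.asarray([lines[start + r].split() for r in range(n_v)], dtype=float)
    faces = np.asarray(
        [lines[start + n_v + r].split()[1:4] for r in range(n_f)], dtype=np.int64
    )
    return SurfaceMesh(verts, faces, name=Path(path).stem)


# ---------------------------------------------------------------------------
# deformation fields


def write_field_csv(field: DeformationField, path):
    rows = ["vertex_index,dx,dy,dz"]
    rows += [
        f"{i},{d[0]:.12g},{d[1]:.12g},{d[2]:.12g}"
        for i, d in enumerate(field.displacements)
    ]
    Path(path).write_text("\n".join(rows) + "\n")


def read_field_csv(path) -> DeformationField:
    raw = np.genfromtxt(str(path), delimiter=",", skip_header=1)
    raw = np.atleast_2d(raw)
    order = np.argsort(raw[:, 0])
    return DeformationField(raw[order, 1:4])


# ---------------------------------------------------------------------------
# radiographs (PNG + JSON sidecar)


def write_drr(drr, path_png, path_json=None):
    import imageio.v3 as iio

    path_png = Path(path_png)
    path_json = Path(path_json) if path_json else path_png.with_suffix(".json")
    pixels = np.asarray(drr.pixels, dtype=float)
    lo, hi = float(pixels.min()), float(pixels.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    iio.imwrite(path_png, ((pixels - lo) * scale).astype(np.uint16))
    meta = {
        "pixel_spacing": list(drr.pixel_spacing),
        "origin": list(drr.origin),
        "intensity_offset": lo,
        "intensity_scale": scale,
        "sad_cm": drr.sad_cm,
        "isocenter_px": list(drr.isocenter_px) if drr.isocenter_px is not None else None,
        "landmarks": {k: list(v) for k, v in (drr.landmarks or {}).items()},
        "heart_contour": drr.heart_contour.tolist() if drr.heart_contour is not None else None,
    }
    path_json.write_text(json.dumps(meta, indent=1))


def read_drr(path_png, path_json=None):
    import imageio.v3 as iio

    from .projection import DRRImage

    path_png = Path(path_png)
    path_json = Path(path_json) if path_json else path_png.with_suffix(".json")
    meta = json.loads(path_json.read_text())
    raw = iio.imread(path_png).astype(float)
    pixels = raw / meta["intensity_scale"] + meta["intensity_offset"]
    return DRRImage(
        pixels=pixels,
        pixel_spacing=tuple(meta["pixel_spacing"]),
        origin=tuple(meta["origin"]),
        isocenter_px=tuple(meta["isocenter_px"]) if meta["isocenter_px"] else None,
        landmarks={k: tuple(v) for k, v in meta["landmarks"].items()},
        heart_contour=np.asarray(meta["heart_contour"]) if meta["heart_contour"] else None,
        sad_cm=meta.get("sad_cm", 100.0),
    )
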