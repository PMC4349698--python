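"""Dental topographic metrics from triangle meshes of molar crowns.

A crown mesh (PLY or OBJ, millimetres, pre-oriented with the occlusal plane
horizontal) yields:

* **TSA** — total 3-D surface area of the crown (sum of triangle areas);
* **PSA** — planometric area of the occlusal-view projection (the *union*
  of the projected triangles, so overlapping cusps are counted once);
* **RFI** — relief index, ``ln(sqrt(TSA) / sqrt(PSA))``;
* **OR**  — occlusal relief, ``TSA / PSA`` of the crown portion above a
  horizontal plane through the lowest point of the talonid basin.

Meshes are expected pre-cropped at the cemento-enamel junction for RFI.
The basin plane for OR can be given explicitly (the primary path, matching
manual practice) or auto-detected from the mesh geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import trimesh
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import unary_union

from occlusal.errors import DomainError, FormatError, InputError

_AXES = {"x": 0, "y": 1, "z": 2}


def _axis_index(up_axis: str) -> int:
    try:
        return _AXES[up_axis.lower()]
    except KeyError:
        raise InputError(f"up_axis must be one of x/y/z, got {up_axis!r}")


@dataclass
class TopographyMetrics:
    """Per-tooth topographic summary (areas in mm^2)."""

    tsa: float
    psa: float
    rfi: float
    or_value: float | None = None
    crop_height: float | None = None


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load a PLY or OBJ triangle mesh; quads are fan-triangulated.

    Coordinates and face structure are preserved (no merging, repair or
    reordering).  Raises :class:`FormatError` on unparsable files.
    """
    path = Path(path)
    try:
        mesh = trimesh.load_mesh(path, process=False)
    except Exception as exc:
        raise FormatError(f"cannot read mesh {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path} contains no triangle faces")
    if not np.isfinite(mesh.vertices).all():
        raise FormatError(f"{path} contains non-finite coordinates")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    """Write a mesh as ascii PLY or OBJ depending on the file suffix."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    elif path.suffix.lower() == ".obj":
        path.write_text(trimesh.exchange.obj.export_obj(mesh))
    else:
        raise InputError(f"unsupported mesh format: {path.suffix}")


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

def total_surface_area(mesh: trimesh.Trimesh) -> float:
    """TSA: sum of triangle areas (degenerate faces contribute zero)."""
    if len(mesh.faces) == 0:
        raise InputError("mesh has no faces")
    v = mesh.vertices.view(np.ndarray)
    f = mesh.faces.view(np.ndarray)
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def projected_area(mesh: trimesh.Trimesh, up_axis: str = "z") -> float:
    """PSA: area of the planar union of all faces projected along ``up_axis``.

    Overlapping projections (e.g. opposite sides of a cusp) count once.
    Raises :class:`InputError` if every face projects to zero area.
    """
    k = _axis_index(up_axis)
    keep = [i for i in range(3) if i != k]
    v2 = mesh.vertices.view(np.ndarray)[:, keep]
    tris = v2[mesh.faces.view(np.ndarray)]
    # signed doubled areas; drop degenerate projections
    a = tris[:, 1] - tris[:, 0]
    b = tris[:, 2] - tris[:, 0]
    area2 = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    scale = max(float(np.abs(v2).max()), 1.0)
    good = np.abs(area2) > 1e-14 * scale**2
    if not good.any():
        raise InputError("degenerate projection: mesh is a vertical sheet")
    polys = shapely.polygons(tris[good])
    union = unary_union(shapely.make_valid(polys))
    return float(union.area)


def projected_area_raster(mesh: trimesh.Trimesh, up_axis: str = "z",
                          resolution: int = 2048) -> float:
    """Rasterization estimate of PSA (fallback for pathological meshes).

    Accurate to about one pixel-row of boundary area at the given grid
    resolution.
    """
    k = _axis_index(up_axis)
    keep = [i for i in range(3) if i != k]
    v2 = mesh.vertices.view(np.ndarray)[:, keep]
    lo = v2.min(axis=0)
    hi = v2.max(axis=0)
    span = float(max(hi - lo))
    if span == 0:
        raise InputError("degenerate projection: mesh is a vertical sheet")
    px = span / resolution
    nx = max(int(np.ceil((hi[0] - lo[0]) / px)), 1)
    ny = max(int(np.ceil((hi[1] - lo[1]) / px)), 1)
    gx = lo[0] + (np.arange(nx) + 0.5) * px
    gy = lo[1] + (np.arange(ny) + 0.5) * px
    covered = np.zeros((ny, nx), dtype=bool)
    tris = v2[mesh.faces.view(np.ndarray)]
    for t in tris:
        d1, d2 = t[1] - t[0], t[2] - t[0]
        det = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(det) < 1e-14:
            continue
        # restrict the barycentric test to the triangle's bounding box
        i0 = np.searchsorted(gx, t[:, 0].min()) - 1
        i1 = np.searchsorted(gx, t[:, 0].max()) + 1
        j0 = np.searchsorted(gy, t[:, 1].min()) - 1
        j1 = np.searchsorted(gy, t[:, 1].max()) + 1
        i0, j0 = max(i0, 0), max(j0, 0)
        XX, YY = np.meshgrid(gx[i0:i1], gy[j0:j1])
        rx, ry = XX - t[0, 0], YY - t[0, 1]
        u = (rx * d2[1] - ry * d2[0]) / det
        w = (ry * d1[0] - rx * d1[1]) / det
        covered[j0:j1, i0:i1] |= (u >= 0) & (w >= 0) & (u + w <= 1)
    return float(covered.sum()) * px * px


def relief_index(tsa: float, psa: float) -> float:
    """RFI = ln(sqrt(TSA)/sqrt(PSA)) = 0.5 * ln(TSA/PSA)."""
    if tsa <= 0 or psa <= 0:
        raise DomainError(f"areas must be positive (tsa={tsa}, psa={psa})")
    if tsa < psa * (1.0 - 1e-9):
        warnings.warn(
            "TSA < PSA: physically impossible for a height-field crown; "
            "check mesh orientation and cropping", stacklevel=2)
    return float(0.5 * np.log(tsa / psa))


# ---------------------------------------------------------------------------
# Basin crop and occlusal relief
# ---------------------------------------------------------------------------

def find_basin_point(mesh: trimesh.Trimesh, up_axis: str = "z",
                     tip_percentile: float = 75.0) -> np.ndarray:
    """Auto-detect the lowest point of the occlusal basin.

    Cusp tips are vertices that are local height maxima (higher than all
    mesh neighbours) above the given height percentile; the basin candidate
    is the lowest vertex whose projection lies strictly inside the 2-D
    convex hull of the tips (the hull is buffered slightly when fewer than
    three tips leave it degenerate).  Ties break toward the lowest vertex
    index.  Manual specification remains the primary path.
    """
    k = _axis_index(up_axis)
    keep = [i for i in range(3) if i != k]
    v = mesh.vertices.view(np.ndarray)
    h = v[:, k]
    cut = np.percentile(h, tip_percentile)

    neighbors = mesh.vertex_neighbors
    tips = [i for i in range(len(v))
            if h[i] > cut and len(neighbors[i]) > 0
            and all(h[i] >= h[j] for j in neighbors[i])
            and any(h[i] > h[j] for j in neighbors[i])]
    if not tips:
        raise InputError("no cusp tips found; supply basin_point explicitly")

    hull = MultiPoint([tuple(v[i, keep]) for i in tips]).convex_hull
    if not isinstance(hull, Polygon):  # <3 tips: buffer to a thin strip
        scale = float(np.ptp(v[:, keep], axis=0).max())
        hull = hull.buffer(0.05 * scale)

    inside = [i for i in range(len(v))
              if hull.contains(shapely.Point(v[i, keep]))]
    inside = [i for i in inside if i not in set(tips)]
    if not inside:
        raise InputError("no basin candidate inside the cusp-tip hull; "
                         "supply basin_point explicitly")
    order = sorted(inside, key=lambda i: (h[i], i))
    return v[order[0]].copy()


def basin_crop(mesh: trimesh.Trimesh,
               basin_point: np.ndarray | int | None = None,
               up_axis: str = "z") -> tuple[trimesh.Trimesh, float]:
    """Crop the mesh at the horizontal plane through the basin point.

    Returns the portion of the mesh at or above the plane (triangles
    straddling it are split exactly) and the plane height.  If the basin
    point is the global minimum, nothing is cut and a warning is issued.
    """
    k = _axis_index(up_axis)
    if basin_point is None:
        basin_point = find_basin_point(mesh, up_axis=up_axis)
    elif np.isscalar(basin_point):
        basin_point = mesh.vertices.view(np.ndarray)[int(basin_point)]
    basin_point = np.asarray(basin_point, dtype=float)
    height = float(basin_point[k])

    h = mesh.vertices.view(np.ndarray)[:, k]
    if height <= h.min() + 1e-12:
        warnings.warn("basin point is the global minimum: nothing to crop",
                      stacklevel=2)
        return mesh.copy(), height

    normal = np.zeros(3)
    normal[k] = 1.0
    cropped = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=normal, plane_origin=basin_point, cap=False)
    if cropped is None or len(cropped.faces) == 0:
        raise InputError("crop removed the entire mesh; check basin point")
    return cropped, height


def occlusal_relief(cropped: trimesh.Trimesh, up_axis: str = "z") -> float:
    """OR = TSA(cropped) / PSA(cropped); 1.0 for a flat table."""
    return total_surface_area(cropped) / projected_area(cropped, up_axis)


def compute_metrics(mesh: trimesh.Trimesh, up_axis: str = "z",
                    with_or: bool = True,
                    basin_point: np.ndarray | int | None = None
                    ) -> TopographyMetrics:
    """TSA, PSA and RFI for a CEJ-cropped crown; optionally basin-crop OR.

    Mirrors the study protocol: OR is meaningful for lower molars (set
    ``with_or=False`` for uppers, whose cingulum variation defeats a
    consistent basin crop).
    """
    tsa = total_surface_area(mesh)
    psa = projected_area(mesh, up_axis)
    rfi = relief_index(tsa, psa)
    or_value = crop_height = None
    if with_or:
        cropped, crop_height = basin_crop(mesh, basin_point, up_axis)
        or_value = occlusal_relief(cropped, up_axis)
    return TopographyMetrics(tsa=tsa, psa=psa, rfi=rfi,
                             or_value=or_value, crop_height=crop_height)
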