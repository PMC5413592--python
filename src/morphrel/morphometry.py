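"""Non-fractal morphometry: surface area, gyrification index, cortical
thickness, structure volume and per-region aggregation.

The gyrification index is the ratio of the (folded) surface area to the area
of a smooth enclosing surface — here computed per closed structure, with the
enclosing surface either the convex hull of the vertices or the boundary of a
morphological closing of the voxelized mesh.  Cortical thickness is the
symmetric nearest-point distance between the white-matter and pial surfaces
(Fischl–Dale style): distances are measured point-to-triangle, not
point-to-vertex, so they are unbiased by the two meshes' vertex densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import BinaryMask, RegionLookup, SurfaceMesh

logger = logging.getLogger(__name__)

HullMethod = Literal["convex_hull", "morphological_closing"]
DEFAULT_CLOSING_RADIUS_MM = 15.0


class GeometryError(ValueError):
    """Degenerate or otherwise unusable geometry."""


class TopologyError(ValueError):
    """Operation requires a closed mesh."""


# ---------------------------------------------------------------------------
# Areas and volumes
# ---------------------------------------------------------------------------

def surface_area(mesh: SurfaceMesh) -> float:
    """Total triangle area in mm^2."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    area = 0.5 * float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())
    if area <= 0:
        raise GeometryError("mesh has zero total area")
    return area


def mask_volume(mask: BinaryMask) -> float:
    """Foreground voxel count times the physical voxel volume (mm^3)."""
    if not mask.data.any():
        raise ValueError("empty mask has no volume")
    return float(mask.count) * float(np.prod(mask.voxel_size_mm))


# ---------------------------------------------------------------------------
# Gyrification index
# ---------------------------------------------------------------------------

@dataclass
class GIResult:
    """Gyrification index and the areas it is built from."""

    gi: float
    cortical_area: float
    hull_area: float
    hull_method: str


def _closing_hull_area(
    mesh: SurfaceMesh, closing_radius_mm: float, pitch_mm: float
) -> float:
    """Area of the boundary of a morphological closing of the voxelized mesh."""
    from skimage.measure import marching_cubes

    tm = mesh.to_trimesh()
    vox = tm.voxelized(pitch=pitch_mm).fill()
    grid = vox.matrix
    r = closing_radius_mm / pitch_mm
    pad = int(np.ceil(r)) + 2
    grid = np.pad(grid, pad)
    if r > 0:
        # Euclidean closing via two distance transforms (a voxelized ball as a
        # structuring element would be prohibitively slow at r ~ 15 voxels)
        dilated = ndimage.distance_transform_edt(~grid) <= r
        grid = ndimage.distance_transform_edt(dilated) >= r  # erode back

    # mild smoothing before the isosurface suppresses the voxel staircase,
    # which otherwise inflates the area by ~10%
    field = ndimage.gaussian_filter(grid.astype(float), sigma=1.5)
    verts, faces, _, _ = marching_cubes(field, level=0.5)
    return surface_area(SurfaceMesh(vertices=verts * pitch_mm, faces=faces))


def gyrification_index(
    mesh: SurfaceMesh,
    hull_method: HullMethod = "convex_hull",
    closing_radius_mm: float = DEFAULT_CLOSING_RADIUS_MM,
    voxel_pitch_mm: float = 1.0,
) -> GIResult:
    """Ratio of surface area to the area of a smooth enclosing surface.

    ``convex_hull`` guarantees gi >= 1 for closed meshes; the
    ``morphological_closing`` hull (voxelize, binary-close with a ball of
    ``closing_radius_mm``, extract the boundary by marching cubes) follows
    folds more closely, as in the local-gyrification literature.
    """
    if not mesh.is_closed():
        raise TopologyError("gyrification index requires a closed mesh")
    cortical = surface_area(mesh)
    if hull_method == "convex_hull":
        hull = mesh.to_trimesh().convex_hull
        hull_area = float(hull.area)
    elif hull_method == "morphological_closing":
        hull_area = _closing_hull_area(mesh, closing_radius_mm, voxel_pitch_mm)
    else:
        raise ValueError(f"unknown hull method {hull_method!r}")
    return GIResult(
        gi=cortical / hull_area,
        cortical_area=cortical,
        hull_area=hull_area,
        hull_method=hull_method,
    )


# ---------------------------------------------------------------------------
# Point-to-triangle distance and cortical thickness
# ---------------------------------------------------------------------------

def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from points[i] to triangle tri[i] (both (N,3)/(N,3,3)).

    Projects onto the triangle plane and clamps to the closest feature
    (face, edge or vertex) via the standard barycentric region test.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    region = (d1 <= 0) & (d2 <= 0)  # vertex a
    closest[region] = a[region]
    done |= region
    region = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex b
    closest[region] = b[region]
    done |= region
    region = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex c
    closest[region] = c[region]
    done |= region

    vc = d1 * d4 - d3 * d2
    region = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    denom = np.where(d1 - d3 == 0, 1.0, d1 - d3)
    t = np.clip(d1 / denom, 0.0, 1.0)
    closest[region] = a[region] + t[region, None] * ab[region]
    done |= region

    vb = d5 * d2 - d1 * d6
    region = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    denom = np.where(d2 - d6 == 0, 1.0, d2 - d6)
    t = np.clip(d2 / denom, 0.0, 1.0)
    closest[region] = a[region] + t[region, None] * ac[region]
    done |= region

    va = d3 * d6 - d5 * d4
    region = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip((d4 - d3) / denom, 0.0, 1.0)
    closest[region] = b[region] + t[region, None] * (c[region] - b[region])
    done |= region

    # interior of the face
    region = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    closest[region] = a[region] + v[region, None] * ab[region] + w[region, None] * ac[region]

    return np.linalg.norm(points - closest, axis=1), closest


def closest_on_surface(
    points: np.ndarray, mesh: SurfaceMesh, k_candidates: int = 24
) -> tuple[np.ndarray, np.ndarray]:
    """Distance and closest point on ``mesh`` for each query point.

    A cKDTree over triangle centroids prefilters to ``k_candidates``
    triangles per point; exact point-to-triangle distances decide among them.
    The candidate set is guaranteed sufficient when the mesh's triangles are
    small relative to the query distance, which holds for the anatomical and
    phantom meshes this package targets; increase ``k_candidates`` for very
    irregular meshes.
    """
    points = np.asarray(points, dtype=float)
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    centroids = tri.mean(axis=1)
    k = min(k_candidates, len(centroids))
    _, idx = cKDTree(centroids).query(points, k=k)
    if k == 1:
        idx = idx[:, None]
    n, _ = idx.shape
    flat_pts = np.repeat(points, k, axis=0)
    flat_tri = tri[idx.ravel()]
    dists, closest = _point_triangle_distance(flat_pts, flat_tri)
    dists = dists.reshape(n, k)
    closest = closest.reshape(n, k, 3)
    best = np.argmin(dists, axis=1)
    rows = np.arange(n)
    return dists[rows, best], closest[rows, best]


def cortical_thickness(white: SurfaceMesh, pial: SurfaceMesh) -> np.ndarray:
    """Per-white-vertex thickness, mm: the symmetric nearest-point scheme.

    For each white vertex w: t(w) = (d(w, pial) + d(p_w, white)) / 2, where
    p_w is the closest point on the pial surface and the second term measures
    back from p_w to the white surface.  The meshes need not share topology.
    Intersecting surfaces legitimately produce zeros (flagged in the log).
    """
    if white.faces.size == 0 or pial.faces.size == 0:
        raise GeometryError("both surfaces must be non-empty meshes")
    d_wp, p_on_pial = closest_on_surface(white.vertices, pial)
    d_back, _ = closest_on_surface(p_on_pial, white)
    thickness = 0.5 * (d_wp + d_back)
    n_zero = int(np.sum(thickness <= 1e-12))
    if n_zero:
        logger.warning("%d vertices have zero thickness (intersecting surfaces?)", n_zero)
    return thickness


# ---------------------------------------------------------------------------
# Regional aggregation
# ---------------------------------------------------------------------------

def regional_mean(
    values: np.ndarray, vertex_labels: np.ndarray, lookup: RegionLookup
) -> pd.DataFrame:
    """Unweighted per-region mean of a per-vertex field.

    Regions from the lookup with no vertices are skipped with a warning.
    """
    values = np.asarray(values, dtype=float)
    vertex_labels = np.asarray(vertex_labels)
    if values.shape != vertex_labels.shape:
        raise ValueError("values and vertex_labels must have the same length")
    rows = []
    for code, name in lookup.entries:
        sel = vertex_labels == code
        n = int(sel.sum())
        if n == 0:
            logger.warning("region %d (%s) has no vertices; skipped", code, name)
            continue
        rows.append({"code": code, "name": name, "mean": float(values[sel].mean()), "n_vertices": n})
    return pd.DataFrame(rows, columns=["code", "name", "mean", "n_vertices"])


__all__ = [
    "GIResult",
    "GeometryError",
    "TopologyError",
    "surface_area",
    "mask_volume",
    "gyrification_index",
    "closest_on_surface",
    "cortical_thickness",
    "regional_mean",
    "DEFAULT_CLOSING_RADIUS_MM",
]
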