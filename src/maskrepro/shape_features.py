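"""Morphological (shape) features of a 3D binary mask, in physical units.

The 14 standard radiomics shape descriptors: mesh volume and surface area of
a marching-cubes isosurface, voxel-count volume, the three principal axis
lengths from the eigenvalues of the foreground-coordinate covariance
(length_i = 4 sqrt(lambda_i)), elongation sqrt(l2/l1) and flatness
sqrt(l3/l1), sphericity (36 pi V^2)^(1/3) / A, and the maximum pairwise
diameter in 3D and in each of the three image planes.

Conventions fixed here (and recorded in :data:`MESH_METHOD`):

* the surface is extracted by marching cubes (Lewiner variant) at iso-level
  0.5 on the zero-padded mask after a light Gaussian anti-aliasing filter
  (sigma 0.8 voxels per axis); vertices are scaled by the voxel spacing so
  all outputs are in mm.  Meshing the raw binary grid inflates surface area
  by ~8% through staircase artifacts; the anti-aliasing step recovers areas
  of smooth bodies to well under 2% while biasing volumes by < 1%.  Masks
  too small or flat to survive the filter (peak below the iso-level) fall
  back to meshing the binary grid directly;
* maximum diameters are measured between mesh vertices (via the convex
  hull, on which the maximum is always attained);
* the coordinate covariance uses voxel centers and divisor N (population
  form), as the 4 sqrt(lambda) axis-length convention presumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from .mask_io import BinaryMask

__all__ = [
    "TriangleMesh",
    "ShapeFeatureVector",
    "FEATURE_NAMES",
    "build_mesh",
    "mesh_volume",
    "surface_area",
    "voxel_volume",
    "axis_lengths",
    "elongation_flatness",
    "max_diameters",
    "sphericity",
    "extract_features",
]

MESH_METHOD = "marching_cubes-lewiner/iso0.5/gauss0.8vox/binary-fallback"
MESH_SMOOTH_SIGMA = 0.8  # voxels, per axis


@dataclass(frozen=True)
class TriangleMesh:
    """A closed triangle surface in mm with outward-oriented faces."""

    vertices: np.ndarray  # (n, 3) float, mm, axes (slice, row, column)
    faces: np.ndarray  # (m, 3) int

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass(frozen=True)
class ShapeFeatureVector:
    """The 14 shape features of one mask.  Undefined entries are NaN."""

    elongation: float
    flatness: float
    least_axis_length: float
    major_axis_length: float
    minor_axis_length: float
    max_2d_diameter_column: float
    max_2d_diameter_row: float
    max_2d_diameter_slice: float
    max_3d_diameter: float
    mesh_volume: float
    voxel_volume: float
    sphericity: float
    surface_area: float
    surface_area_to_volume_ratio: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


FEATURE_NAMES = [f.name for f in fields(ShapeFeatureVector)]


def build_mesh(mask: BinaryMask) -> TriangleMesh:
    """Triangulated isosurface of a non-empty mask, vertices in mm.

    The mask is cropped to its bounding box and zero-padded so the surface
    is always closed; vertex coordinates are index x spacing, offset so they
    are consistent with the full grid.
    """
    if mask.count == 0:
        raise ValueError("cannot mesh an empty mask")
    idx = np.nonzero(mask.voxels)
    lo = [int(a.min()) for a in idx]
    hi = [int(a.max()) + 1 for a in idx]
    cropped = mask.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    pad = int(np.ceil(3 * MESH_SMOOTH_SIGMA)) + 1
    padded = np.pad(cropped, pad).astype(np.float64)
    # filter in float64, then quantize: the separable filter's axis-order
    # rounding would otherwise break exact symmetry under axis permutation
    smoothed = ndimage.gaussian_filter(padded, MESH_SMOOTH_SIGMA).astype(np.float32)
    padded = padded.astype(np.float32)
    if smoothed.max() <= 0.5:  # mask too small/thin for anti-aliasing
        smoothed = padded
    # mesh in index space, then scale to mm in float64 so that spacing
    # rescaling is exact (marching_cubes emits float32 vertices)
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5)
    verts = verts.astype(np.float64) * np.asarray(mask.spacing)
    offset = (np.asarray(lo, dtype=float) - pad) * np.asarray(mask.spacing)
    verts = verts + offset
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if tm.volume < 0:  # orientation depends on the marching-cubes normal convention
        faces = faces[:, ::-1]
    return TriangleMesh(np.asarray(verts, dtype=float), np.asarray(faces))


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume in mm^3 via signed tetrahedra (divergence theorem)."""
    tm = mesh.as_trimesh()
    if not tm.is_watertight:
        raise ValueError("mesh is not watertight; volume undefined")
    if not tm.is_winding_consistent:
        raise ValueError("inconsistent face orientation; signed volume undefined")
    vol = float(tm.volume)
    if vol <= 0:
        raise ValueError(f"non-positive signed volume ({vol:g}); check face orientation")
    return vol


def surface_area(mesh: TriangleMesh) -> float:
    """Total triangle area in mm^2."""
    area = float(mesh.as_trimesh().area)
    if area <= 0:
        raise ValueError("degenerate mesh with zero surface area")
    return area


def voxel_volume(mask: BinaryMask) -> float:
    """Foreground voxel count times the voxel volume, mm^3."""
    if mask.count == 0:
        raise ValueError("empty mask has no volume")
    return mask.count * float(np.prod(mask.spacing))


def _coords_mm(mask: BinaryMask) -> np.ndarray:
    idx = np.column_stack(np.nonzero(mask.voxels)).astype(float)
    return idx * np.asarray(mask.spacing)


def _cov_eigenvalues(mask: BinaryMask) -> np.ndarray:
    """Eigenvalues (descending) of the population covariance of voxel centers."""
    coords = _coords_mm(mask)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    lam = np.linalg.eigvalsh(cov)[::-1]
    return np.clip(lam, 0.0, None)


def axis_lengths(mask: BinaryMask) -> tuple[float, float, float]:
    """(major, minor, least) axis lengths, 4 sqrt(lambda_i), in mm."""
    if mask.count == 0:
        raise ValueError("empty mask")
    l1, l2, l3 = _cov_eigenvalues(mask)
    return 4 * np.sqrt(l1), 4 * np.sqrt(l2), 4 * np.sqrt(l3)


def elongation_flatness(mask: BinaryMask) -> tuple[float, float]:
    """(sqrt(l2/l1), sqrt(l3/l1)); NaN with a warning for a single voxel."""
    if mask.count == 0:
        raise ValueError("empty mask")
    l1, l2, l3 = _cov_eigenvalues(mask)
    if l1 <= 0:
        warnings.warn("zero principal variance (single voxel?); elongation/flatness undefined")
        return float("nan"), float("nan")
    return float(np.sqrt(l2 / l1)), float(np.sqrt(l3 / l1))


def _max_pairwise(points: np.ndarray) -> float:
    """Maximum pairwise distance, via the convex hull when possible."""
    pts = np.unique(points, axis=0)
    if len(pts) < 2:
        return 0.0
    if len(pts) > pts.shape[1] + 1:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear): brute force on all points
    return float(pdist(pts).max())


def max_diameters(mesh: TriangleMesh) -> tuple[float, float, float, float]:
    """(d3d, d_slice, d_column, d_row) maximum diameters in mm.

    d3d is over all vertex pairs; each 2D diameter drops one coordinate:
    slice-plane = row x column, column-plane = slice x row,
    row-plane = slice x column.
    """
    verts = mesh.vertices
    try:
        hull_pts = verts[ConvexHull(verts).vertices]
    except QhullError:
        hull_pts = verts
    d3d = _max_pairwise(hull_pts)
    d_slice = _max_pairwise(hull_pts[:, [1, 2]])
    d_column = _max_pairwise(hull_pts[:, [0, 1]])
    d_row = _max_pairwise(hull_pts[:, [0, 2]])
    return d3d, d_slice, d_column, d_row


def sphericity(volume: float, area: float) -> float:
    """(36 pi V^2)^(1/3) / A; equals 1 for a perfect sphere."""
    if volume <= 0 or area <= 0:
        raise ValueError("sphericity requires positive volume and area")
    return float((36 * np.pi * volume**2) ** (1 / 3) / area)


def extract_features(mask: BinaryMask) -> ShapeFeatureVector:
    """Compute all 14 shape features of a non-empty mask.

    Deterministic for a fixed input; degenerate masks (single voxel, planar)
    yield NaN for the undefined ratio features and zero axis lengths rather
    than an exception.
    """
    if mask.count == 0:
        raise ValueError("cannot extract features from an empty mask")
    mesh = build_mesh(mask)
    vol = mesh_volume(mesh)
    area = surface_area(mesh)
    major, minor, least = axis_lengths(mask)
    elong, flat = elongation_flatness(mask)
    d3d, d_slice, d_column, d_row = max_diameters(mesh)
    return ShapeFeatureVector(
        elongation=elong,
        flatness=flat,
        least_axis_length=float(least),
        major_axis_length=float(major),
        minor_axis_length=float(minor),
        max_2d_diameter_column=d_column,
        max_2d_diameter_row=d_row,
        max_2d_diameter_slice=d_slice,
        max_3d_diameter=d3d,
        mesh_volume=vol,
        voxel_volume=voxel_volume(mask),
        sphericity=sphericity(vol, area),
        surface_area=area,
        surface_area_to_volume_ratio=area / vol,
    )
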