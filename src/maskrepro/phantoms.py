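"""Digitized geometric phantoms with closed-form ground truth.

Rasterized ellipsoids, spheres, and boxes on regular voxel grids, plus the
analytic volume and surface-area formulas they are checked against.  Used
throughout the test suite: a digitized solid ellipsoid has known volume
(4/3 pi abc), surface area (Legendre incomplete elliptic integrals), and
coordinate-covariance eigenvalues (semi-axis^2 / 5), so every shape feature
has an independent analytic oracle.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ellipeinc, ellipkinc

from .mask_io import BinaryMask, Region

__all__ = [
    "digitized_ellipsoid",
    "digitized_sphere",
    "digitized_box",
    "ellipsoid_volume",
    "ellipsoid_surface_area",
]


def digitized_ellipsoid(
    semi_axes: tuple[float, float, float],
    spacing: tuple[float, float, float],
    margin: int = 5,
    shift: tuple[int, int, int] = (0, 0, 0),
) -> BinaryMask:
    """Solid axis-aligned ellipsoid rasterized at voxel centers.

    ``semi_axes`` are in mm, ordered (slice, row, column) like the grid;
    ``margin`` adds background voxels per side and ``shift`` translates the
    center by whole voxels (for translation-invariance checks).
    """
    shape = [int(2 * a / s) + 2 * margin + 1 for a, s in zip(semi_axes, spacing)]
    center = [(n - 1) / 2.0 + d for n, d in zip(shape, shift)]
    grids = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    rho2 = sum(
        ((g - c) * s / a) ** 2 for g, c, s, a in zip(grids, center, spacing, semi_axes)
    )
    return BinaryMask(rho2 <= 1.0, tuple(spacing), region=Region.WP)


def digitized_sphere(radius: float, spacing: float, **kw) -> BinaryMask:
    """Solid sphere at isotropic spacing."""
    return digitized_ellipsoid((radius,) * 3, (spacing,) * 3, **kw)


def digitized_box(
    extents: tuple[float, float, float],
    spacing: tuple[float, float, float],
    margin: int = 5,
) -> BinaryMask:
    """Solid axis-aligned box with the given physical edge lengths (mm)."""
    counts = [int(round(e / s)) for e, s in zip(extents, spacing)]
    shape = [c + 2 * margin for c in counts]
    vox = np.zeros(shape, dtype=bool)
    vox[
        margin : margin + counts[0],
        margin : margin + counts[1],
        margin : margin + counts[2],
    ] = True
    return BinaryMask(vox, tuple(spacing), region=Region.WP)


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """4/3 pi abc, mm^3."""
    return 4.0 / 3.0 * np.pi * a * b * c


def ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Exact ellipsoid surface area via incomplete elliptic integrals."""
    a, b, c = sorted((a, b, c), reverse=True)
    if abs(a - c) < 1e-12 * a:
        return 4.0 * np.pi * a * a
    phi = np.arccos(c / a)
    m = (a**2 * (b**2 - c**2)) / (b**2 * (a**2 - c**2))
    f = ellipkinc(phi, m)
    e = ellipeinc(phi, m)
    return float(
        2 * np.pi * c**2
        + 2 * np.pi * a * b / np.sin(phi) * (e * np.sin(phi) ** 2 + f * np.cos(phi) ** 2)
    )
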