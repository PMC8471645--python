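import numpy as np
import pytest

from maskrepro.mask_io import BinaryMask
from maskrepro.phantoms import (
    digitized_box,
    digitized_ellipsoid,
    digitized_sphere,
    ellipsoid_surface_area,
    ellipsoid_volume,
)
from maskrepro.shape_features import (
    FEATURE_NAMES,
    TriangleMesh,
    axis_lengths,
    build_mesh,
    elongation_flatness,
    extract_features,
    max_diameters,
    mesh_volume,
    sphericity,
    surface_area,
    voxel_volume,
)

# hand-built unit cube: 8 vertices, 12 outward-oriented triangles
_CUBE_VERTS = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
)
_CUBE_FACES = np.array(
    [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
     [0, 1, 5], [0, 5, 4], [1, 2, 6], [1, 6, 5],
     [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
)


def unit_cube_mesh() -> TriangleMesh:
    return TriangleMesh(_CUBE_VERTS.copy(), _CUBE_FACES.copy())


class TestMeshPrimitives:
    def test_unit_cube_closed_forms(self):
        mesh = unit_cube_mesh()
        assert mesh_volume(mesh) == pytest.approx(1.0)
        assert surface_area(mesh) == pytest.approx(6.0)
        assert sphericity(1.0, 6.0) == pytest.approx((36 * np.pi) ** (1 / 3) / 6, abs=1e-5)

    def test_flipped_face_detected(self):
        faces = _CUBE_FACES.copy()
        faces[0] = faces[0, ::-1]
        with pytest.raises(ValueError):
            mesh_volume(TriangleMesh(_CUBE_VERTS.copy(), faces))

    def test_disjoint_cubes_areas_add(self):
        shifted = _CUBE_VERTS + np.array([5.0, 0.0, 0.0])
        mesh = TriangleMesh(
            np.vstack([_CUBE_VERTS, shifted]), np.vstack([_CUBE_FACES, _CUBE_FACES + 8])
        )
        assert surface_area(mesh) == pytest.approx(12.0)

    def test_single_voxel_mesh_regression(self):
        # frozen values of the chosen marching-cubes variant (binary fallback)
        mask = BinaryMask(np.ones((1, 1, 1)), (1.0, 1.0, 1.0))
        mesh = build_mesh(mask)
        assert mesh_volume(mesh) == pytest.approx(1 / 6, abs=1e-12)
        d3d, ds, dc, dr = max_diameters(mesh)
        assert (d3d, ds, dc, dr) == pytest.approx((1.0, 1.0, 1.0, 1.0))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            build_mesh(BinaryMask(np.zeros((2, 2, 2), bool), (1, 1, 1)))

    def test_sphere_mesh_watertight_ball_topology(self):
        mesh = build_mesh(digitized_sphere(10.0, 1.0))
        tm = mesh.as_trimesh()
        assert tm.is_watertight
        assert tm.euler_number == 2


class TestVoxelFeatures:
    def test_voxel_volume_arithmetic(self):
        vox = np.zeros((20, 20, 20), bool)
        vox.ravel()[:1000] = True
        assert voxel_volume(BinaryMask(vox, (3.0, 0.5, 0.5))) == pytest.approx(750.0)
        assert voxel_volume(BinaryMask(np.ones((1, 1, 1)), (1, 1, 1))) == pytest.approx(1.0)

    def test_ellipsoid_axis_lengths_match_analytic(self):
        mask = digitized_ellipsoid((30, 20, 10), (0.5, 0.5, 0.5))
        major, minor, least = axis_lengths(mask)
        assert major == pytest.approx(4 * 30 / np.sqrt(5), rel=0.02)
        assert minor == pytest.approx(4 * 20 / np.sqrt(5), rel=0.02)
        assert least == pytest.approx(4 * 10 / np.sqrt(5), rel=0.02)
        elong, flat = elongation_flatness(mask)
        assert elong == pytest.approx(2 / 3, rel=0.02)
        assert flat == pytest.approx(1 / 3, rel=0.02)

    def test_planar_mask_rank_deficient(self):
        vox = np.zeros((5, 6, 6), bool)
        vox[2, 1:5, 1:5] = True
        _, _, least = axis_lengths(BinaryMask(vox, (1, 1, 1)))
        assert least == 0.0
        _, flat = elongation_flatness(BinaryMask(vox, (1, 1, 1)))
        assert flat == 0.0

    def test_single_voxel_degenerate(self):
        m = BinaryMask(np.ones((1, 1, 1)), (1, 1, 1))
        assert axis_lengths(m) == (0.0, 0.0, 0.0)
        with pytest.warns(UserWarning, match="undefined"):
            elong, flat = elongation_flatness(m)
        assert np.isnan(elong) and np.isnan(flat)


class TestExtractFeatures:
    def test_sphere_against_analytic(self):
        fv = extract_features(digitized_sphere(10.0, 0.5))
        assert 0.97 <= fv.sphericity <= 1.005
        assert fv.mesh_volume == pytest.approx(ellipsoid_volume(10, 10, 10), rel=0.01)
        assert fv.voxel_volume == pytest.approx(ellipsoid_volume(10, 10, 10), rel=0.01)
        assert fv.surface_area == pytest.approx(4 * np.pi * 100, rel=0.02)
        for d in (fv.max_3d_diameter, fv.max_2d_diameter_slice,
                  fv.max_2d_diameter_row, fv.max_2d_diameter_column):
            assert d == pytest.approx(20.0, rel=0.02)
        assert fv.elongation == pytest.approx(1.0, rel=0.02)
        assert fv.surface_area_to_volume_ratio == pytest.approx(
            fv.surface_area / fv.mesh_volume
        )

    def test_box_diameters(self):
        fv = extract_features(digitized_box((30, 20, 10), (0.5, 0.5, 0.5)))
        assert fv.max_3d_diameter == pytest.approx(np.sqrt(30**2 + 20**2 + 10**2), rel=0.03)
        assert fv.max_2d_diameter_slice == pytest.approx(np.sqrt(20**2 + 10**2), rel=0.03)
        assert fv.max_2d_diameter_column == pytest.approx(np.sqrt(30**2 + 20**2), rel=0.03)
        assert fv.max_2d_diameter_row == pytest.approx(np.sqrt(30**2 + 10**2), rel=0.03)

    def test_translation_invariance_exact(self):
        a = digitized_ellipsoid((9, 7, 5), (1.0, 1.0, 1.0), margin=12)
        b = digitized_ellipsoid((9, 7, 5), (1.0, 1.0, 1.0), margin=12, shift=(7, -3, 2))
        fa, fb = extract_features(a).to_dict(), extract_features(b).to_dict()
        for name in FEATURE_NAMES:
            assert fa[name] == pytest.approx(fb[name], rel=0, abs=1e-12), name

    def test_spacing_scaling_laws(self):
        base = digitized_ellipsoid((9, 7, 5), (1.0, 1.0, 1.0))
        s = 2.5
        scaled = BinaryMask(base.voxels, tuple(s * np.array(base.spacing)))
        fa, fb = extract_features(base).to_dict(), extract_features(scaled).to_dict()
        powers = {
            "mesh_volume": 3, "voxel_volume": 3, "surface_area": 2,
            "surface_area_to_volume_ratio": -1,
            "major_axis_length": 1, "minor_axis_length": 1, "least_axis_length": 1,
            "max_3d_diameter": 1, "max_2d_diameter_slice": 1,
            "max_2d_diameter_row": 1, "max_2d_diameter_column": 1,
            "elongation": 0, "flatness": 0, "sphericity": 0,
        }
        for name, p in powers.items():
            assert fb[name] == pytest.approx(fa[name] * s**p, rel=1e-9), name

    def test_axis_permutation_permutes_plane_diameters(self):
        mask = digitized_ellipsoid((13, 9, 6), (1.0, 1.0, 1.0))
        perm = (1, 2, 0)  # new (slice,row,col) = old (row,col,slice)
        rotated = BinaryMask(np.transpose(mask.voxels, perm), mask.spacing)
        fa, fb = extract_features(mask).to_dict(), extract_features(rotated).to_dict()
        invariant = ["mesh_volume", "voxel_volume", "surface_area", "sphericity",
                     "max_3d_diameter", "major_axis_length", "minor_axis_length",
                     "least_axis_length", "elongation", "flatness",
                     "surface_area_to_volume_ratio"]
        for name in invariant:
            assert fb[name] == pytest.approx(fa[name], rel=1e-5), name
        # dropping the new slice axis == dropping the old row axis, etc.
        assert fb["max_2d_diameter_slice"] == pytest.approx(fa["max_2d_diameter_row"], rel=1e-5)
        assert fb["max_2d_diameter_row"] == pytest.approx(fa["max_2d_diameter_column"], rel=1e-5)
        assert fb["max_2d_diameter_column"] == pytest.approx(fa["max_2d_diameter_slice"], rel=1e-5)

    def test_mesh_volume_close_to_voxel_volume_for_smooth_body(self):
        fv = extract_features(digitized_sphere(10.0, 1.0))
        assert fv.mesh_volume == pytest.approx(fv.voxel_volume, rel=0.05)

    def test_anisotropic_spacing_ellipsoid_volume(self):
        fv = extract_features(digitized_ellipsoid((21, 20, 23), (3.0, 0.5, 0.5)))
        assert fv.mesh_volume == pytest.approx(ellipsoid_volume(21, 20, 23), rel=0.02)

    def test_ellipsoid_sphericity_below_one(self):
        fv = extract_features(digitized_ellipsoid((30, 20, 10), (1.0, 1.0, 1.0)))
        assert fv.sphericity < 1.0

    def test_deterministic(self):
        mask = digitized_ellipsoid((8, 6, 5), (1.0, 1.0, 1.0))
        assert extract_features(mask) == extract_features(mask)
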