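"""Reading, writing, and region extraction for 3D zonal label maps.

A :class:`LabelVolume` is a 3D integer grid with the fixed label convention
``0 = background, 1 = peripheral zone (PZ), 2 = remaining zones (non-PZ)``.
The whole gland (WP) is the union of the two foreground labels.  Volumes are
stored slice-first (slice x row x column) with voxel spacing in millimetres
per axis in the same order; NIfTI files are reoriented to a canonical
anatomical orientation on load so that plane-dependent features (the 2D
maximum diameters) are well defined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "LabelVolume",
    "BinaryMask",
    "PairedCohort",
    "read_label_volume",
    "write_label_volume",
    "extract_region",
    "subtract_masks",
    "compose_wp_pz",
    "read_manifest",
]

BACKGROUND, PZ_LABEL, NONPZ_LABEL = 0, 1, 2
VALID_LABELS = frozenset({BACKGROUND, PZ_LABEL, NONPZ_LABEL})


class Region(str, enum.Enum):
    """The three analysis regions of the prostate gland."""

    WP = "WP"
    PZ = "PZ"
    NONPZ = "nonPZ"


@dataclass(frozen=True)
class LabelVolume:
    """A 3D zonal label map with physical metadata.

    Parameters
    ----------
    voxels
        Integer array, axes ordered slice x row x column, values in {0,1,2}.
    spacing
        Voxel size in mm per axis, same order as ``voxels``.
    origin
        Physical position (mm) of voxel (0, 0, 0).
    subject_id, scan_id, method_id
        Identity of the segmentation this volume holds.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    subject_id: str = ""
    scan_id: str = "scan1"
    method_id: str = "manual"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or vox.size == 0:
            raise ValueError("label volume must be a non-empty 3D grid")
        if not np.issubdtype(vox.dtype, np.integer):
            if not np.array_equal(vox, np.round(vox)):
                raise ValueError("label volume must be integer-valued")
            vox = vox.astype(np.int16)
        bad = np.setdiff1d(np.unique(vox), sorted(VALID_LABELS))
        if bad.size:
            raise ValueError(f"invalid label values {bad.tolist()}; expected subset of {{0,1,2}}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A single-region boolean mask sharing grid and spacing with its source."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    region: Region = Region.WP

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3 or vox.size == 0:
            raise ValueError("mask must be a non-empty 3D grid")
        if vox.dtype != bool:
            vox = vox.astype(bool)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "region", Region(self.region))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.voxels.sum())


def _check_same_grid(a, b) -> None:
    if a.voxels.shape != b.voxels.shape:
        raise ValueError(f"grid shape mismatch: {a.voxels.shape} vs {b.voxels.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def read_label_volume(
    path: str | Path,
    subject_id: str = "",
    scan_id: str = "scan1",
    method_id: str = "manual",
) -> LabelVolume:
    """Read a NIfTI label map and canonicalize to slice x row x column order.

    The image is reoriented to the closest RAS orientation, then transposed so
    that the slowest axis is the slice axis.  Spacing is taken from the header,
    the origin from the affine translation.  Labels outside {0,1,2} are an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.array_equal(data, np.round(data)):
            raise ValueError("invalid label: non-integer voxel values")
        data = np.round(data).astype(np.int16)
    zooms = img.header.get_zooms()[:3]
    origin_xyz = img.affine[:3, 3]
    # NIfTI canonical axes are (x, y, z); slice-first order is (z, y, x)
    voxels = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = (float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0]))
    return LabelVolume(voxels, spacing, origin, subject_id, scan_id, method_id)


def write_label_volume(lv: LabelVolume, path: str | Path) -> Path:
    """Write a LabelVolume as NIfTI-1; inverse of :func:`read_label_volume`."""
    path = Path(path)
    data = np.transpose(lv.voxels.astype(np.int16), (2, 1, 0))
    affine = np.diag([lv.spacing[2], lv.spacing[1], lv.spacing[0], 1.0])
    affine[:3, 3] = (lv.origin[2], lv.origin[1], lv.origin[0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((lv.spacing[2], lv.spacing[1], lv.spacing[0]))
    nib.save(img, str(path))
    return path


def extract_region(lv: LabelVolume, region: Region | str) -> BinaryMask:
    """Derive one of the three region masks from a label volume.

    PZ is label 1, non-PZ label 2, and WP their merge (any foreground label),
    so the WP foreground count is the sum of the zonal counts.
    """
    region = Region(region)
    if region is Region.PZ:
        vox = lv.voxels == PZ_LABEL
    elif region is Region.NONPZ:
        vox = lv.voxels == NONPZ_LABEL
    else:
        vox = lv.voxels > 0
    return BinaryMask(vox, lv.spacing, lv.origin, region)


def subtract_masks(wp: BinaryMask, pz: BinaryMask) -> BinaryMask:
    """Set difference WP minus PZ; PZ voxels outside WP are ignored."""
    _check_same_grid(wp, pz)
    return BinaryMask(wp.voxels & ~pz.voxels, wp.spacing, wp.origin, Region.NONPZ)


def compose_wp_pz(wp: BinaryMask, pz: BinaryMask, **ids: str) -> LabelVolume:
    """Build a label volume from independently produced WP and PZ masks.

    Supports segmentation methods that predict WP and PZ separately: non-PZ is
    WP minus PZ, and PZ voxels falling outside WP are clipped to WP (dropped),
    the conservative set-difference reading.
    """
    _check_same_grid(wp, pz)
    pz_in = wp.voxels & pz.voxels
    labels = np.zeros(wp.voxels.shape, dtype=np.int16)
    labels[wp.voxels] = NONPZ_LABEL
    labels[pz_in] = PZ_LABEL
    return LabelVolume(labels, wp.spacing, wp.origin, **ids)


MANIFEST_COLUMNS = ["subject_id", "scan_id", "method_id", "path"]


@dataclass
class PairedCohort:
    """A subject x scan x method collection of label volumes.

    ``volumes`` maps ``(subject_id, scan_id, method_id)`` to a LabelVolume;
    ``quality_scores`` optionally maps ``(subject_id, scan_id)`` to a 0-100
    segmentation quality score used for cohort filtering.
    """

    volumes: dict[tuple[str, str, str], LabelVolume]
    quality_scores: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return sorted({k[0] for k in self.volumes})

    @property
    def scan_ids(self) -> list[str]:
        return sorted({k[1] for k in self.volumes})

    @property
    def method_ids(self) -> list[str]:
        return sorted({k[2] for k in self.volumes})

    def get(self, subject_id: str, scan_id: str, method_id: str) -> LabelVolume:
        return self.volumes[(subject_id, scan_id, method_id)]

    def complete_subjects(self, scan_ids: Iterable[str] | None = None,
                          method_ids: Iterable[str] | None = None) -> list[str]:
        """Subjects that have every (scan, method) combination present."""
        scans = list(scan_ids) if scan_ids is not None else self.scan_ids
        methods = list(method_ids) if method_ids is not None else self.method_ids
        return [
            s for s in self.subject_ids
            if all((s, sc, m) in self.volumes for sc in scans for m in methods)
        ]

    def to_manifest(self, directory: str | Path) -> pd.DataFrame:
        """Write every volume as NIfTI under ``directory`` plus a manifest CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for (sid, scan, method), lv in sorted(self.volumes.items()):
            fname = f"{sid}_{scan}_{method}.nii.gz"
            write_label_volume(lv, directory / fname)
            row = {"subject_id": sid, "scan_id": scan, "method_id": method, "path": fname}
            if (sid, scan) in self.quality_scores:
                row["quality_score"] = self.quality_scores[(sid, scan)]
            rows.append(row)
        manifest = pd.DataFrame(rows)
        manifest.to_csv(directory / "manifest.csv", index=False)
        return manifest


def read_manifest(manifest_path: str | Path) -> PairedCohort:
    """Load a cohort from a manifest CSV (columns: subject_id, scan_id,
    method_id, path, optional quality_score); paths are resolved relative to
    the manifest's directory."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    root = manifest_path.parent
    volumes: dict[tuple[str, str, str], LabelVolume] = {}
    scores: dict[tuple[str, str], float] = {}
    for rec in df.itertuples(index=False):
        sid, scan, method = str(rec.subject_id), str(rec.scan_id), str(rec.method_id)
        p = Path(rec.path)
        if not p.is_absolute():
            p = root / p
        volumes[(sid, scan, method)] = read_label_volume(p, sid, scan, method)
        if hasattr(rec, "quality_score") and not pd.isna(rec.quality_score):
            scores[(sid, scan)] = float(rec.quality_score)
    return PairedCohort(volumes, scores)
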