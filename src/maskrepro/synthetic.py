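"""Synthetic paired two-scan, multi-method segmentation cohorts.

The generator emulates the structure of a prostate test-retest study: each
subject has a whole-gland (WP) ground truth modelled as a superellipsoid
with a posterior shell for the peripheral zone (PZ), imaged twice.  The
second scan compresses the gland along the anterior-posterior axis (an
endorectal probe and prone positioning deform the shape) while preserving
its volume through compensatory in-plane scaling, and may lose an end slice
(segmenters include one slice fewer).  Each segmentation method's mask is
the ground truth perturbed by a smooth random radial boundary-displacement
field whose amplitude (in mm) encodes that method's error level, optionally
plus a small disconnected spurious component and, rarely, a gross failure
(over/under-segmentation by several mm).  Per-subject, per-scan quality
scores on a 0-100 scale are fabricated to correlate negatively with the
injected error, standing in for an external segmentation quality-control
model.

Closed-form ground truth makes the generator auditable: axis ratios,
volumes, and the compression-induced shape change are known analytically,
so downstream statistics can be tested against designed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.special import gamma as _gamma

from .mask_io import LabelVolume, PairedCohort

__all__ = ["SyntheticConfig", "SyntheticSubject", "generate_subject", "generate_cohort",
           "superellipsoid_volume_factor"]

SCANS = ("scan1", "scan2")


def superellipsoid_volume_factor(p: float) -> float:
    """V = factor * a*b*c for the superellipsoid |x/a|^p+|y/b|^p+|z/c|^p <= 1."""
    return 8.0 * _gamma(1 + 1 / p) ** 3 / _gamma(1 + 3 / p)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the paired-biopsy cohort design: 62 subjects, 3 mm
    slices with 0.5 mm in-plane spacing, glands of ~42 cm^3 spanning about
    14 axial slices, a manual reference plus three CNN-like methods with
    graded boundary-error amplitudes, and a ~10% anterior-posterior
    compression of the gland in scan 2.
    """

    n_subjects: int = 62
    spacing: tuple[float, float, float] = (3.0, 0.5, 0.5)  # slice, row, column (mm)
    wp_volume_mean: float = 42000.0  # mm^3, lognormal across subjects
    wp_volume_sd: float = 12000.0
    axis_ratio_range: tuple[float, float] = (0.78, 0.98)  # row/col and slice/col semi-axis ratios
    pz_thickness_fraction: float = 0.35  # posterior shell thickness, fraction of radius
    scan2_compression: float = 0.90  # anterior-posterior semi-axis scale in scan 2
    scan2_slice_dropout_prob: float = 0.4
    method_noise: Mapping[str, float] = field(
        default_factory=lambda: {"manual": 0.4, "nnunet3d": 0.7, "nnunet2d": 1.0, "vnet": 2.2}
    )  # boundary-displacement amplitude per method, mm
    spurious_component_prob: float = 0.15  # per non-manual method mask
    gross_failure_prob: float = 0.05  # per non-manual method mask
    quality_score_noise: float = 3.0  # SD of the score's additive noise
    noise_correlation_mm: float = 8.0  # correlation length of the boundary field
    superellipsoid_exponent: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scan2_slice_dropout_prob", "spurious_component_prob", "gross_failure_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.5 < self.scan2_compression <= 1.0:
            raise ValueError("scan2_compression must lie in (0.5, 1]")
        if "manual" not in self.method_noise or len(self.method_noise) < 2:
            raise ValueError("method_noise must include 'manual' plus >= 1 simulated method")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not 0.0 < self.pz_thickness_fraction < 1.0:
            raise ValueError("pz_thickness_fraction must lie in (0, 1)")
        object.__setattr__(self, "method_noise", dict(self.method_noise))


@dataclass
class SyntheticSubject:
    """One generated subject: ground-truth parameters, masks, quality scores."""

    subject_id: str
    true_params: dict  # per scan: semi_axes (slice,row,col mm), center, exponent
    label_volumes: dict[tuple[str, str], LabelVolume]  # (scan_id, method_id) -> volume
    quality_scores: dict[str, float]  # scan_id -> score


def _subject_rng(config: SyntheticConfig, subject_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(subject_index,))
    return np.random.default_rng(ss)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2, np.sqrt(s2)


def _signed_distance(grids, semi_axes, p):
    """Approximate signed distance (mm) to a superellipsoid surface."""
    z, y, x = grids
    a_s, a_r, a_c = semi_axes
    rho = (
        np.abs(z / a_s) ** p + np.abs(y / a_r) ** p + np.abs(x / a_c) ** p
    ) ** (1.0 / p)
    r = np.sqrt(z * z + y * y + x * x)
    return np.where(rho > 1e-9, (rho - 1.0) * r / np.maximum(rho, 1e-9), -min(semi_axes))


def _smooth_field(rng, shape, spacing, corr_mm, amplitude):
    """Zero-mean smooth random field with unit SD scaled to ``amplitude`` mm,
    softly clipped at 2.5x amplitude so displacements stay bounded.

    The field is synthesized on a lattice coarsened well below the
    correlation length and linearly upsampled, which leaves its statistics
    unchanged at a fraction of the filtering cost.
    """
    factor = [max(1, min(4, int(corr_mm / (3.0 * s)))) for s in spacing]
    coarse_shape = [-(-n // f) + 1 for n, f in zip(shape, factor)]
    field = rng.standard_normal(coarse_shape)
    sigma = [corr_mm / (s * f) for s, f in zip(spacing, factor)]
    field = ndimage.gaussian_filter(field, sigma=sigma, mode="nearest")
    if any(f > 1 for f in factor):
        field = ndimage.zoom(field, factor, order=1, grid_mode=True, mode="nearest")
    field = field[: shape[0], : shape[1], : shape[2]]
    sd = field.std()
    if sd < 1e-12:
        return np.zeros(shape)
    field *= amplitude / sd
    bound = 2.5 * amplitude
    return bound * np.tanh(field / bound)


def _direction_radius(direction, semi_axes, p) -> float:
    """Surface radius of the superellipsoid along a unit direction."""
    d = np.abs(np.asarray(direction, dtype=float))
    a = np.asarray(semi_axes, dtype=float)
    return float(np.sum((d / a) ** p) ** (-1.0 / p))


def generate_subject(config: SyntheticConfig, subject_index: int) -> SyntheticSubject:
    """Generate one subject deterministically from the master seed.

    Each subject draws from an independent RNG stream spawned from
    ``config.seed`` and its index, so subjects are individually reproducible
    regardless of batch size.
    """
    rng = _subject_rng(config, subject_index)
    sid = f"S{subject_index:03d}"
    p = config.superellipsoid_exponent
    vol_factor = superellipsoid_volume_factor(p)

    mu, sigma = _lognormal_params(config.wp_volume_mean, config.wp_volume_sd)
    volume = float(rng.lognormal(mu, sigma))
    q_row = float(rng.uniform(*config.axis_ratio_range))
    q_slice = float(rng.uniform(*config.axis_ratio_range))
    a_col = (volume / (vol_factor * q_row * q_slice)) ** (1.0 / 3.0)
    axes1 = np.array([q_slice * a_col, q_row * a_col, a_col])  # slice, row, col
    c = config.scan2_compression
    # compress anterior-posterior (row), preserve volume via the other axes
    axes2 = axes1 * np.array([1.0 / np.sqrt(c), c, 1.0 / np.sqrt(c)])
    semi = {"scan1": axes1, "scan2": axes2}

    amp_max = max(config.method_noise.values())
    blob_r_max = (3.0 * 0.01 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    pad_inplane = 2.5 * amp_max + 4.5 + 2.0 * blob_r_max + 3.0
    pad_slice = 2.5 * amp_max + 4.5
    a_env = np.maximum(axes1, axes2)
    half = a_env + np.array([pad_slice, pad_inplane, pad_inplane])
    sp = np.asarray(config.spacing)
    shape = tuple(int(np.ceil(2 * h / s)) | 1 for h, s in zip(half, sp))  # odd dims
    # sub-voxel center jitter (same for both scans) so rasterization is not
    # artificially symmetric about a voxel center
    jitter = rng.uniform(-0.5, 0.5, size=3) * sp
    center = (np.asarray(shape) - 1) / 2.0 * sp + jitter
    grids = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    grids = [g * s - cc for g, s, cc in zip(grids, sp, center)]

    inner_scale = 1.0 - config.pz_thickness_fraction
    posterior = grids[1] > 0  # broadcastable along the row axis

    label_volumes: dict[tuple[str, str], LabelVolume] = {}
    scan_error: dict[str, list[float]] = {s: [] for s in SCANS}
    scan_gross: dict[str, bool] = {s: False for s in SCANS}

    for scan in SCANS:
        d_wp = _signed_distance(grids, semi[scan], p)
        d_in = _signed_distance(grids, semi[scan] * inner_scale, p)
        for method, amp in config.method_noise.items():
            simulated = method != "manual"
            if amp > 0:
                g_wp = _smooth_field(rng, shape, sp, config.noise_correlation_mm, amp)
                g_in = _smooth_field(rng, shape, sp, config.noise_correlation_mm, amp)
            else:
                g_wp = g_in = 0.0

            delta = 0.0
            if simulated and rng.uniform() < config.gross_failure_prob:
                delta = float(rng.choice([-1.0, 1.0]) * (3.0 + rng.uniform()))
                scan_gross[scan] = True

            wp_m = d_wp <= g_wp + delta
            inner_m = d_in <= g_in + delta
            labels = np.zeros(shape, dtype=np.int8)
            labels[wp_m] = 2
            labels[wp_m & ~inner_m & posterior] = 1

            if simulated and rng.uniform() < config.spurious_component_prob:
                frac = rng.uniform(0.003, 0.01)
                r_blob = (3.0 * frac * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
                theta = rng.uniform(0, 2 * np.pi)
                direction = np.array([0.0, np.sin(theta), np.cos(theta)])
                gap = 2.5 * amp + 3.0 + max(delta, 0.0)
                dist = _direction_radius(direction, semi[scan], p) + gap + r_blob
                blob_center = direction * dist
                bd = np.sqrt(
                    grids[0] ** 2
                    + (grids[1] - blob_center[1]) ** 2
                    + (grids[2] - blob_center[2]) ** 2
                )
                blob = (bd <= r_blob) & (labels == 0)
                labels[blob] = int(rng.choice([1, 2]))

            if (
                scan == "scan2"
                and rng.uniform() < config.scan2_slice_dropout_prob
            ):
                occupied = np.flatnonzero(labels.any(axis=(1, 2)))
                if occupied.size > 3:
                    labels[occupied[-1]] = 0

            if simulated:
                scan_error[scan].append(amp + abs(delta))
            label_volumes[(scan, method)] = LabelVolume(
                labels, tuple(sp), (0.0, 0.0, 0.0), sid, scan, method
            )

    quality_scores = {}
    for scan in SCANS:
        errs = scan_error[scan] or [config.method_noise["manual"]]
        score = (
            100.0
            - 2.5 * float(np.mean(errs))
            - 18.0 * scan_gross[scan]
            + rng.normal(0.0, config.quality_score_noise)
        )
        quality_scores[scan] = float(np.clip(score, 0.0, 100.0))

    true_params = {
        scan: {"semi_axes": tuple(semi[scan]), "center": tuple(center), "exponent": p}
        for scan in SCANS
    }
    return SyntheticSubject(sid, true_params, label_volumes, quality_scores)


def generate_cohort(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> PairedCohort:
    """Generate the full cohort; optionally write NIfTI files plus a manifest.

    Returns an in-memory :class:`PairedCohort`.  When ``out_dir`` is given,
    every volume is written as NIfTI-1 and a ``manifest.csv`` (one row per
    subject x scan x method, with quality scores) is placed alongside.
    """
    volumes: dict[tuple[str, str, str], LabelVolume] = {}
    scores: dict[tuple[str, str], float] = {}
    for i in range(config.n_subjects):
        subj = generate_subject(config, i)
        for (scan, method), lv in subj.label_volumes.items():
            volumes[(subj.subject_id, scan, method)] = lv
        for scan, score in subj.quality_scores.items():
            scores[(subj.subject_id, scan)] = score
    cohort = PairedCohort(volumes, scores)
    if out_dir is not None:
        cohort.to_manifest(out_dir)
    return cohort
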