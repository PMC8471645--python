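"""End-to-end reproducibility analysis of a paired segmentation cohort.

Orchestrates the stage chain: load cohort -> (optional) largest-component
post-processing -> per-region shape-feature extraction -> agreement
statistics (per-feature ICC(2,1) with CI, DSC vs the reference method,
inter-scan volume comparison with Wilcoxon/Benjamini-Hochberg, Bland-Altman
and Spearman, CI-overlap significance vs the reference) -> optional
quality-score filtering with its permutation test.  Everything is emitted as
tidy tables keyed by (region, method, feature) so any stage can be audited
independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    ICCResult,
    MeasurementTable,
    bh_adjust,
    bland_altman,
    ci_overlap_significant,
    dsc,
    icc_two_way_random_single,
    percent_median_difference,
    spearman,
    wilcoxon_signed_rank,
)
from .mask_io import PairedCohort, Region, extract_region, read_manifest
from .postprocess import postprocess_label_volume
from .qc import QualityScoredCohort, apply_quality_filter, permutation_icc_test
from .shape_features import FEATURE_NAMES, MESH_METHOD, extract_features

__all__ = ["AnalysisReport", "run_analysis", "compare_methods", "extract_feature_table"]

logger = logging.getLogger(__name__)

REGIONS = [Region.WP, Region.PZ, Region.NONPZ]
SCANS = ("scan1", "scan2")


@dataclass
class AnalysisReport:
    """Tidy result tables of one analysis run plus provenance metadata."""

    feature_table: pd.DataFrame
    icc_table: pd.DataFrame
    dsc_summary: pd.DataFrame
    volume_comparison: pd.DataFrame
    bland_altman_table: pd.DataFrame
    significance: pd.DataFrame
    qc_results: pd.DataFrame
    provenance: dict

    def icc(self, region: str, method: str, feature: str) -> ICCResult:
        """Look up one ICC entry as an :class:`ICCResult`."""
        t = self.icc_table
        row = t[(t.region == str(region)) & (t.method == method) & (t.feature == feature)]
        if row.empty:
            raise KeyError((region, method, feature))
        r = row.iloc[0]
        return ICCResult(r.icc, r.ci_low, r.ci_high, int(r.n), 2)

    def to_dir(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("feature_table", "icc_table", "dsc_summary", "volume_comparison",
                     "bland_altman_table", "significance", "qc_results"):
            getattr(self, name).to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "provenance.json").write_text(json.dumps(self.provenance, indent=2))
        return out_dir


def extract_feature_table(
    cohort: PairedCohort,
    postprocess: bool = True,
    reference: str = "manual",
    methods: list[str] | None = None,
    connectivity: int = 26,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the per-mask shape-feature table and per-mask DSC records.

    Returns ``(features, dsc_records)``: one feature row per
    (subject, scan, method, region) and one DSC row per non-reference
    (subject, scan, method, region) against the reference segmentation of
    the same subject and scan.  Masks left empty (a region a method failed
    to segment) produce NaN feature rows with a warning in the log.
    """
    methods = sorted(methods) if methods is not None else cohort.method_ids
    subjects = cohort.complete_subjects(SCANS, methods)
    dropped = sorted(set(cohort.subject_ids) - set(subjects))
    if dropped:
        logger.warning("excluding %d subjects with incomplete scan/method pairs: %s",
                       len(dropped), dropped)
    feat_rows, dsc_rows = [], []
    for sid in subjects:
        for scan in SCANS:
            masks: dict[tuple[str, Region], object] = {}
            for method in methods:
                lv = cohort.get(sid, scan, method)
                if postprocess:
                    lv = postprocess_label_volume(lv, connectivity)
                for region in REGIONS:
                    mask = extract_region(lv, region)
                    masks[(method, region)] = mask
                    row = {"subject_id": sid, "scan_id": scan, "method_id": method,
                           "region": region.value}
                    if mask.count == 0:
                        logger.warning("empty %s mask: subject=%s scan=%s method=%s",
                                       region.value, sid, scan, method)
                        row.update({f: np.nan for f in FEATURE_NAMES})
                    else:
                        row.update(extract_features(mask).to_dict())
                    feat_rows.append(row)
            if reference in methods:
                for method in methods:
                    if method == reference:
                        continue
                    for region in REGIONS:
                        a = masks[(reference, region)]
                        b = masks[(method, region)]
                        val = np.nan if a.count + b.count == 0 else dsc(a, b)
                        dsc_rows.append({"subject_id": sid, "scan_id": scan,
                                         "method_id": method, "region": region.value,
                                         "dsc": val})
    features = pd.DataFrame(feat_rows)
    dsc_records = pd.DataFrame(
        dsc_rows, columns=["subject_id", "scan_id", "method_id", "region", "dsc"]
    )
    return features, dsc_records


def _paired_values(features: pd.DataFrame, region: str, method: str,
                   feature: str, subjects: list[str]) -> np.ndarray:
    sub = features[(features.region == region) & (features.method_id == method)
                   & (features.subject_id.isin(subjects))]
    wide = sub.pivot(index="subject_id", columns="scan_id", values=feature)
    wide = wide.reindex(columns=list(SCANS)).sort_index()
    return wide.to_numpy(dtype=float)


def run_analysis(
    cohort: PairedCohort | str | Path,
    postprocess: bool = True,
    qc_threshold: float | None = None,
    reference: str = "manual",
    methods: list[str] | None = None,
    qc_feature: str = "voxel_volume",
    runs: int = 1000,
    seed: int = 0,
    bh_family: str = "region",
    connectivity: int = 26,
) -> AnalysisReport:
    """Run the full reproducibility analysis and return its report tables.

    Parameters mirror the study's three analysis variants: ``postprocess``
    toggles the largest-component cleanup, ``qc_threshold`` (e.g. 85)
    enables quality-score exclusion with a permutation test of the resulting
    ICC improvement, and the default leaves filtering off.  ``bh_family``
    chooses whether Benjamini-Hochberg pools p-values per region (default)
    or across all regions ("pooled").  Deterministic for a given seed.
    """
    if not isinstance(cohort, PairedCohort):
        cohort = read_manifest(cohort)
    methods = sorted(methods) if methods is not None else cohort.method_ids
    features, dsc_records = extract_feature_table(
        cohort, postprocess=postprocess, reference=reference, methods=methods,
        connectivity=connectivity,
    )
    all_subjects = sorted(features.subject_id.unique())

    qc_rows = []
    kept = all_subjects
    excluded: list[str] = []
    if qc_threshold is not None and cohort.quality_scores:
        qsc = QualityScoredCohort(
            tuple(all_subjects),
            np.array([cohort.quality_scores[(s, "scan1")] for s in all_subjects]),
            np.array([cohort.quality_scores[(s, "scan2")] for s in all_subjects]),
            threshold=qc_threshold,
        )
        kept, excluded = apply_quality_filter(qsc)
        logger.info("quality filter at %.0f excluded %d/%d subjects",
                    qc_threshold, len(excluded), len(all_subjects))

    icc_rows = []
    for region in REGIONS:
        for method in methods:
            for feature in FEATURE_NAMES:
                values = _paired_values(features, region.value, method, feature, kept)
                table = MeasurementTable(values, feature, method, region.value)
                try:
                    res = icc_two_way_random_single(table)
                    icc_rows.append({"region": region.value, "method": method,
                                     "feature": feature, "icc": res.icc,
                                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                                     "n": res.n_subjects})
                except ValueError:
                    icc_rows.append({"region": region.value, "method": method,
                                     "feature": feature, "icc": np.nan,
                                     "ci_low": np.nan, "ci_high": np.nan,
                                     "n": len(table.complete_cases())})
    icc_table = pd.DataFrame(icc_rows)

    dsc_rows_out = []
    if not dsc_records.empty:
        use = dsc_records[dsc_records.subject_id.isin(kept)]
        for (region, method, scan), grp in use.groupby(["region", "method_id", "scan_id"]):
            vals = grp.dsc.dropna()
            if vals.empty:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            dsc_rows_out.append({"region": region, "method": method, "scan": scan,
                                 "median": med, "iqr_low": q1, "iqr_high": q3,
                                 "n": len(vals)})
    dsc_summary = pd.DataFrame(
        dsc_rows_out, columns=["region", "method", "scan", "median", "iqr_low",
                               "iqr_high", "n"]
    )

    vol_rows, ba_rows = [], []
    for region in REGIONS:
        for method in methods:
            pair = _paired_values(features, region.value, method, "voxel_volume", kept)
            pair = pair[~np.isnan(pair).any(axis=1)]
            if len(pair) < 5 or np.any(pair[:, 0] <= 0):
                continue
            s1, s2 = pair[:, 0], pair[:, 1]
            ba = bland_altman(s1, s2)
            rho, sp_p = spearman(s1, s2)
            vol_rows.append({"region": region.value, "method": method,
                             "percent_median_difference": percent_median_difference(s1, s2),
                             "wilcoxon_p": wilcoxon_signed_rank(s1, s2), "n": len(s1)})
            ba_rows.append({"region": region.value, "comparison": f"{method}:scan2-scan1",
                            "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                            "spearman_rho": rho, "spearman_p": sp_p, "n": ba.n})
        # method-vs-reference volume agreement within each scan
        for method in methods:
            if method == reference or reference not in methods:
                continue
            for scan in SCANS:
                sub = features[(features.region == region.value)
                               & (features.scan_id == scan)
                               & (features.subject_id.isin(kept))]
                wide = sub.pivot(index="subject_id", columns="method_id",
                                 values="voxel_volume")
                if reference not in wide or method not in wide:
                    continue
                wide = wide[[reference, method]].dropna()
                if len(wide) < 5:
                    continue
                ref_v = wide[reference].to_numpy()
                m_v = wide[method].to_numpy()
                ba = bland_altman(ref_v, m_v)
                rho, sp_p = spearman(ref_v, m_v)
                ba_rows.append({"region": region.value,
                                "comparison": f"{method}-{reference}:{scan}",
                                "bias": ba.bias, "loa_low": ba.loa_low,
                                "loa_high": ba.loa_high, "spearman_rho": rho,
                                "spearman_p": sp_p, "n": ba.n})
    volume_comparison = pd.DataFrame(
        vol_rows, columns=["region", "method", "percent_median_difference",
                           "wilcoxon_p", "n"]
    )
    if not volume_comparison.empty:
        if bh_family == "pooled":
            volume_comparison["bh_q"] = bh_adjust(volume_comparison.wilcoxon_p)
        else:
            volume_comparison["bh_q"] = np.nan
            for region, idx in volume_comparison.groupby("region").groups.items():
                volume_comparison.loc[idx, "bh_q"] = bh_adjust(
                    volume_comparison.loc[idx, "wilcoxon_p"]
                )
    bland_altman_table = pd.DataFrame(
        ba_rows, columns=["region", "comparison", "bias", "loa_low", "loa_high",
                          "spearman_rho", "spearman_p", "n"]
    )

    significance = _significance_table(icc_table, methods, reference)

    if qc_threshold is not None and excluded:
        combos = [(r.value, m) for r in REGIONS for m in methods]
        for j, (region, method) in enumerate(combos):
            full = _paired_values(features, region, method, qc_feature, all_subjects)
            full = full[~np.isnan(full).any(axis=1)]
            after = _paired_values(features, region, method, qc_feature, kept)
            after = after[~np.isnan(after).any(axis=1)]
            n_excl = len(full) - len(after)
            if len(after) < 4 or n_excl == 0 or n_excl >= len(full) - 3:
                continue
            child = int(np.random.SeedSequence(entropy=seed, spawn_key=(j,))
                        .generate_state(1)[0] % (2**31))
            observed = icc_two_way_random_single(after).icc
            res = permutation_icc_test(full, n_excl, observed, runs=runs, seed=child)
            qc_rows.append({"region": region, "method": method, "feature": qc_feature,
                            "observed_icc_after": res.observed_icc_after,
                            "n_excluded": res.n_excluded, "runs": res.runs,
                            "n_ge": res.n_ge, "significant": res.significant,
                            "seed": res.seed})
    qc_results = pd.DataFrame(
        qc_rows, columns=["region", "method", "feature", "observed_icc_after",
                          "n_excluded", "runs", "n_ge", "significant", "seed"]
    )

    key_digest = hashlib.md5(
        ",".join(f"{k[0]}|{k[1]}|{k[2]}" for k in sorted(cohort.volumes)).encode()
    ).hexdigest()
    provenance = {
        "software": f"maskrepro {__version__}",
        "mesh_method": MESH_METHOD,
        "seed": seed,
        "postprocess": postprocess,
        "connectivity": connectivity,
        "qc_threshold": qc_threshold,
        "reference": reference,
        "methods": methods,
        "bh_family": bh_family,
        "n_subjects": len(all_subjects),
        "n_kept": len(kept),
        "excluded_subjects": excluded,
        "cohort_digest": key_digest,
    }
    return AnalysisReport(features, icc_table, dsc_summary, volume_comparison,
                          bland_altman_table, significance, qc_results, provenance)


def _significance_table(icc_table: pd.DataFrame, methods: list[str],
                        reference: str) -> pd.DataFrame:
    rows = []
    if reference not in methods:
        return pd.DataFrame(columns=["region", "method", "feature", "icc", "reference_icc",
                                     "significant", "comparable"])
    for region in icc_table.region.unique():
        for method in methods:
            if method == reference:
                continue
            for feature in FEATURE_NAMES:
                t = icc_table
                a = t[(t.region == region) & (t.method == method) & (t.feature == feature)]
                b = t[(t.region == region) & (t.method == reference) & (t.feature == feature)]
                if a.empty or b.empty or np.isnan(a.iloc[0].icc) or np.isnan(b.iloc[0].icc):
                    continue
                ra = ICCResult(a.iloc[0].icc, a.iloc[0].ci_low, a.iloc[0].ci_high,
                               int(a.iloc[0].n), 2)
                rb = ICCResult(b.iloc[0].icc, b.iloc[0].ci_low, b.iloc[0].ci_high,
                               int(b.iloc[0].n), 2)
                sig = ci_overlap_significant(ra, rb)
                rows.append({"region": region, "method": method, "feature": feature,
                             "icc": ra.icc, "reference_icc": rb.icc, "significant": sig,
                             "comparable": (not sig) or ra.icc >= rb.icc})
    return pd.DataFrame(rows, columns=["region", "method", "feature", "icc",
                                       "reference_icc", "significant", "comparable"])


def compare_methods(report: AnalysisReport, reference: str = "manual") -> pd.DataFrame:
    """Per-method, per-region count of features comparable to the reference.

    A feature is comparable when its ICC confidence interval overlaps the
    reference method's, or when the method's ICC is at least as high.
    Returns rows (region, method, n_comparable, n_features) in the
    "k/14 features" style summary.
    """
    methods = report.provenance["methods"]
    if reference not in methods:
        raise ValueError(f"unknown reference method {reference!r}")
    detail = _significance_table(report.icc_table, methods, reference)
    if detail.empty:
        raise ValueError("report contains no comparable ICC entries")
    rows = []
    for (region, method), grp in detail.groupby(["region", "method"]):
        rows.append({"region": region, "method": method,
                     "n_comparable": int(grp.comparable.sum()),
                     "n_features": int(len(grp))})
    return pd.DataFrame(rows)
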