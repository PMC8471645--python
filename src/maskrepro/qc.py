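"""Quality-score cohort filtering and the permutation test for its effect.

A per-subject, per-scan segmentation quality score (0-100, produced by any
external quality-control model) drives cohort exclusion: a subject is
dropped when either scan scores below the threshold (default 85).  Whether
the resulting ICC improvement is more than random-exclusion luck is assessed
by a permutation test: the same number of subjects is excluded uniformly at
random many times, and the observed post-filter ICC is compared against the
permuted ICC distribution.  With 1000 runs the improvement is significant
when fewer than 50 permuted values are >= the observed one (a one-sided 5%
rule; ties count against significance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agreement import MeasurementTable, icc_point_batch

__all__ = ["QualityScoredCohort", "PermutationResult", "apply_quality_filter",
           "permutation_icc_test"]

DEFAULT_THRESHOLD = 85.0


@dataclass(frozen=True)
class QualityScoredCohort:
    """Per-subject quality scores for both scans, plus the exclusion threshold."""

    subject_ids: tuple[str, ...]
    scores_scan1: np.ndarray
    scores_scan2: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        s1 = np.asarray(self.scores_scan1, dtype=float)
        s2 = np.asarray(self.scores_scan2, dtype=float)
        if not (len(self.subject_ids) == len(s1) == len(s2)):
            raise ValueError("one score per subject per scan required")
        for s in (s1, s2):
            if np.any((s < 0) | (s > 100)):
                raise ValueError("quality scores must lie in [0, 100]")
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "scores_scan1", s1)
        object.__setattr__(self, "scores_scan2", s2)


@dataclass(frozen=True)
class PermutationResult:
    observed_icc_after: float
    n_excluded: int
    runs: int
    n_ge: int
    significant: bool
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_ge <= self.runs:
            raise ValueError("n_ge must lie in [0, runs]")


def apply_quality_filter(cohort: QualityScoredCohort) -> tuple[list[str], list[str]]:
    """Split subjects into (kept, excluded) by the strict-less-than OR rule.

    A subject is excluded iff its score on scan 1 OR scan 2 is strictly below
    the threshold; a score exactly at the threshold is kept.
    """
    t = cohort.threshold
    bad = (cohort.scores_scan1 < t) | (cohort.scores_scan2 < t)
    kept = [s for s, b in zip(cohort.subject_ids, bad) if not b]
    excluded = [s for s, b in zip(cohort.subject_ids, bad) if b]
    return kept, excluded


def permutation_icc_test(
    table: MeasurementTable | np.ndarray,
    n_excluded: int,
    observed_icc_after: float,
    runs: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Random-exclusion permutation test for a quality-filtered ICC.

    Each run excludes ``n_excluded`` subjects (both scans together, the same
    unit the quality filter removes) drawn uniformly without replacement from
    the full table, and recomputes ICC(2,1) on the remainder.  Subjects are
    sampled with ``numpy.random.default_rng(seed)`` via one
    ``rng.choice(n, n_excluded, replace=False)`` call per run, in run order,
    so results replay exactly for a given seed.
    """
    if not isinstance(table, MeasurementTable):
        table = MeasurementTable(table)
    values = table.complete_cases()
    n = values.shape[0]
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if not -1.0 <= observed_icc_after <= 1.0:
        raise ValueError("observed ICC must lie in [-1, 1]")
    if not 0 < n_excluded < n - 3:
        raise ValueError(
            f"n_excluded must leave > 3 subjects: got {n_excluded} of {n}"
        )
    rng = np.random.default_rng(seed)
    all_idx = np.arange(n)
    keep = np.empty((runs, n - n_excluded), dtype=np.intp)
    for r in range(runs):
        drop = rng.choice(n, size=n_excluded, replace=False)
        keep[r] = np.setdiff1d(all_idx, drop)
    perm_icc = icc_point_batch(values, keep)
    n_ge = int(np.count_nonzero(perm_icc >= observed_icc_after))
    significant = n_ge < 0.05 * runs
    return PermutationResult(float(observed_icc_after), int(n_excluded), int(runs),
                             n_ge, bool(significant), int(seed))
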