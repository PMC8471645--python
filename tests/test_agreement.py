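from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maskrepro.agreement import (
    ICCResult,
    MeasurementTable,
    bh_adjust,
    bland_altman,
    ci_overlap_significant,
    dsc,
    icc_point,
    icc_point_batch,
    icc_two_way_random_single,
    percent_median_difference,
    spearman,
    wilcoxon_signed_rank,
)
from maskrepro.mask_io import BinaryMask

from conftest import random_mask


def icc21_sums_of_squares_oracle(values: np.ndarray) -> float:
    """Brute-force two-way ANOVA via explicit elementwise sums (test oracle)."""
    n, k = values.shape
    grand = sum(values[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(values[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(values[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((values[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestDSC:
    def test_identical_masks(self, rng):
        m = random_mask(rng)
        assert dsc(m, m) == pytest.approx(1.0)

    def test_disjoint_masks(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.zeros((3, 3, 3), bool)
        a[0], b[2] = True, True
        assert dsc(BinaryMask(a, (1, 1, 1)), BinaryMask(b, (1, 1, 1))) == 0.0

    def test_half_overlap(self):
        a = np.zeros((2, 2, 2), bool)
        b = np.zeros((2, 2, 2), bool)
        a.ravel()[:4] = True
        b.ravel()[2:6] = True
        assert dsc(BinaryMask(a, (1, 1, 1)), BinaryMask(b, (1, 1, 1))) == pytest.approx(0.5)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(25):
            a, b = random_mask(rng), random_mask(rng)
            d = dsc(a, b)
            assert 0.0 <= d <= 1.0
            assert d == dsc(b, a)
            assert (d == 1.0) == np.array_equal(a.voxels, b.voxels)

    def test_both_empty_is_error(self):
        e = BinaryMask(np.zeros((2, 2, 2), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            dsc(e, e)


class TestICC:
    def test_hand_worked_table(self):
        table = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]])
        assert icc_point(table) == pytest.approx(2 / 3, abs=1e-12)

    def test_duplicate_column_perfect_agreement(self, rng):
        x = rng.normal(size=10)
        res = icc_two_way_random_single(np.column_stack([x, x]))
        assert res.icc == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        vals = rng.standard_normal((1000, 2))
        assert abs(icc_point(vals)) < 0.1

    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(300):
            vals = rng.standard_normal((10, 2)) + rng.standard_normal((10, 1))
            assert icc_point(vals) == pytest.approx(
                icc21_sums_of_squares_oracle(vals), abs=1e-10
            )

    def test_matches_pingouin_estimate_and_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(5):
            n = 25
            vals = rng.standard_normal((n, 2)) + 1.2 * rng.standard_normal((n, 1))
            df = pd.DataFrame({
                "subj": np.repeat(np.arange(n), 2),
                "rater": np.tile([0, 1], n),
                "y": vals.ravel(),
            })
            ref = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
            ref = ref[ref.Type == "ICC(A,1)"].iloc[0] if "ICC(A,1)" in set(ref.Type) \
                else ref[ref.Type == "ICC2"].iloc[0]
            mine = icc_two_way_random_single(vals)
            assert mine.icc == pytest.approx(float(ref.ICC), abs=1e-10)
            lo, hi = ref.CI95 if hasattr(ref, "CI95") else ref["CI95%"]
            assert mine.ci_low == pytest.approx(float(lo), abs=0.01)
            assert mine.ci_high == pytest.approx(float(hi), abs=0.01)

    def test_affine_invariance(self, rng):
        vals = rng.standard_normal((15, 2)) + rng.standard_normal((15, 1))
        base = icc_point(vals)
        assert icc_point(vals + 17.3) == pytest.approx(base, abs=1e-10)
        assert icc_point(vals * 4.2) == pytest.approx(base, abs=1e-10)

    def test_degenerate_constant_table(self):
        with pytest.warns(UserWarning, match="zero total variance"):
            res = icc_two_way_random_single(np.full((5, 2), 3.7))
        assert (res.icc, res.ci_low, res.ci_high) == (1.0, 1.0, 1.0)

    def test_complete_case_exclusion(self, rng):
        vals = rng.standard_normal((10, 2)) + rng.standard_normal((10, 1))
        with_nan = vals.copy()
        with_nan[3, 1] = np.nan
        res = icc_two_way_random_single(MeasurementTable(with_nan))
        expected = icc_two_way_random_single(np.delete(vals, 3, axis=0))
        assert res.icc == pytest.approx(expected.icc)
        assert res.n_subjects == 9

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match=">= 3"):
            icc_two_way_random_single(np.ones((2, 2)))

    def test_batch_matches_scalar(self, rng):
        vals = rng.standard_normal((12, 2)) + rng.standard_normal((12, 1))
        keep = np.array([[0, 1, 2, 3, 4], [5, 6, 7, 8, 9], [2, 4, 6, 8, 10]])
        batch = icc_point_batch(vals, keep)
        for row, expected in zip(keep, batch):
            assert icc_point(vals[row]) == pytest.approx(expected, abs=1e-12)

    def test_parameter_recovery(self, rng):
        for true_icc in (0.3, 0.8):
            sigma_s = np.sqrt(true_icc)
            sigma_e = np.sqrt(1 - true_icc)
            ests = []
            for _ in range(20):
                s = rng.normal(0, sigma_s, (500, 1))
                e = rng.normal(0, sigma_e, (500, 2))
                ests.append(icc_point(s + e))
            assert np.mean(ests) == pytest.approx(true_icc, abs=0.05)


class TestCIOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0.6, 0.5, 0.7), (0.85, 0.8, 0.9), True),
            ((0.6, 0.5, 0.85), (0.85, 0.8, 0.9), False),
            ((0.6, 0.5, 0.8), (0.85, 0.8, 0.9), False),  # touching endpoint overlaps
        ],
    )
    def test_disjointness_rule(self, a, b, expected):
        ra = ICCResult(a[0], a[1], a[2], 10, 2)
        rb = ICCResult(b[0], b[1], b[2], 10, 2)
        assert ci_overlap_significant(ra, rb) is expected
        assert ci_overlap_significant(rb, ra) is expected


class TestWilcoxon:
    def test_no_signal(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank(x, x) == 1.0

    def test_strong_shift(self):
        x = np.arange(20.0)
        assert wilcoxon_signed_rank(x, x + 1) < 0.001

    def test_exact_enumeration_oracle(self):
        diffs = np.array([1.0, -2.0, 3.0, -4.0, 5.0, 6.0])
        x = np.zeros(6)
        p = wilcoxon_signed_rank(x, diffs)
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
        w_obs = ranks[diffs > 0].sum()
        dist = [sum(r for r, s in zip(ranks, signs) if s)
                for signs in product((False, True), repeat=6)]
        dist = np.array(dist)
        p_exact = 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean())
        assert p == pytest.approx(min(p_exact, 1.0), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_dominates_raw_and_preserves_order(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestSpearman:
    def test_monotone_maps(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        d2 = sum((a - b) ** 2 for a, b in zip([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))
        assert d2 == 4
        assert rho == pytest.approx(1 - 6 * d2 / (5 * 24))
        assert rho == pytest.approx(0.8)

    def test_constant_input_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)


class TestBlandAltman:
    def test_constant_differences(self):
        res = bland_altman([10, 20, 30], [12, 22, 32])
        assert (res.bias, res.loa_low, res.loa_high) == pytest.approx((2.0, 2.0, 2.0))

    def test_identity(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.bias, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)

    def test_hand_sd(self):
        res = bland_altman([0.0, 0.0], [-1.0, 1.0])
        assert res.bias == 0.0
        assert res.loa_high == pytest.approx(1.96 * np.sqrt(2.0))
        assert res.loa_low == pytest.approx(-1.96 * np.sqrt(2.0))


class TestPercentMedianDifference:
    def test_cases(self):
        s1 = np.array([100.0, 200.0, 300.0])
        assert percent_median_difference(s1, s1) == 0.0
        assert percent_median_difference(s1, 0.9 * s1) == pytest.approx(-10.0)
        assert percent_median_difference(s1, [90.0, 210.0, 240.0]) == pytest.approx(-10.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_median_difference([0.0, 1.0], [1.0, 1.0])
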