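"""Statistical battery against independent brute-force oracles: midrank
Spearman, exact signed-rank enumeration, ANOVA mean-squares ICC, and the
Bland-Altman formulas."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from lungdens import (
    BhallaRecord,
    bhalla_total,
    bland_altman,
    cohort_report,
    icc,
    interpret_r,
    spearman,
    wilcoxon_paired,
)
from lungdens.errors import UndefinedStatisticError, ValidationError


def midrank(v):
    """Brute-force midranks: average position of equal values."""
    v = np.asarray(v, float)
    return np.array([(np.sum(v < x) + 1 + np.sum(v <= x)) / 2.0 for x in v])


class TestSpearman:
    def test_monotone_relationships(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        assert spearman(x, np.exp(x / 5)).r == pytest.approx(1.0)
        assert spearman(x, -(x**3)).r == pytest.approx(-1.0)

    def test_matches_midrank_pearson_oracle(self):
        x = np.array([1, 2, 3, 4, 5], float)
        y = np.array([2, 1, 4, 3, 5], float)
        rx, ry = midrank(x), midrank(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).r == pytest.approx(oracle, abs=1e-12)

    def test_ties_use_midranks(self):
        x = np.array([1, 2, 2, 3, 4], float)
        y = np.array([10, 30, 20, 20, 50], float)
        oracle = np.corrcoef(midrank(x), midrank(y))[0, 1]
        assert spearman(x, y).r == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman(x, y).r
        assert spearman(np.exp(x), y).r == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).r == pytest.approx(base, abs=1e-12)

    def test_exact_permutation_p_close_to_t_approximation(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7], float)
        y = np.array([2, 1, 4, 3, 6, 5, 7], float)
        exact = spearman(x, y, method="exact").p
        approx = spearman(x, y, method="t").p
        assert exact == pytest.approx(approx, abs=0.05)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1, 2], [2, 1])


class TestInterpretR:
    @pytest.mark.parametrize(
        "r,band",
        [
            (-0.65, "good"),
            (0.20, "absent to weak"),
            (0.85, "strong"),
            (0.39, "absent to weak"),
            (0.40, "moderate"),
            (0.59, "moderate"),
            (0.60, "good"),
            (-0.79, "good"),
            (0.80, "strong"),
            (1.0, "strong"),
        ],
    )
    def test_bands(self, r, band):
        assert interpret_r(r) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            interpret_r(1.2)


def enumerate_signed_rank(d):
    """Exhaustive oracle: two-sided p of the signed-rank statistic over all
    2^n sign assignments, midranks for tied |d|."""
    d = np.asarray(d, float)
    d = d[d != 0]
    absd = np.abs(d)
    ranks = midrank(absd)
    total = ranks.sum()
    w_obs = ranks[d > 0].sum()
    dist = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        dist.append(np.dot(signs, ranks))
    dist = np.array(dist)
    return np.mean(np.abs(dist - total / 2) >= np.abs(w_obs - total / 2) - 1e-12)


class TestWilcoxon:
    def test_constant_positive_offset_matches_enumeration(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a + 2.5  # all differences equal: maximal ties
        stat, p = wilcoxon_paired(a, b)
        assert stat == 0.0  # minimal one-sided statistic
        assert p == pytest.approx(enumerate_signed_rank(a - b), abs=1e-12)
        assert p == pytest.approx(2 / 64)

    def test_tie_free_small_sample_matches_enumeration(self):
        a = np.array([5.0, 3.0, 8.0, 9.0, 1.0, 7.0, 4.0, 6.5])
        b = np.array([4.0, 3.5, 6.0, 9.5, 0.0, 5.0, 4.8, 6.0])
        _, p = wilcoxon_paired(a, b)
        assert p == pytest.approx(enumerate_signed_rank(a - b), abs=1e-12)

    def test_antisymmetric_differences_have_high_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        d = np.array([3.0, -3.0, 1.5, -1.5, 0.5, -0.5])
        _, p = wilcoxon_paired(a + d, a)
        assert p == pytest.approx(enumerate_signed_rank(d), abs=1e-12)
        assert p == 1.0  # perfectly balanced signs sit at the null center

    def test_all_zero_differences_undefined(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(UndefinedStatisticError):
            wilcoxon_paired(a, a.copy())


def icc21_oracle(r):
    """Direct mean-squares arithmetic for ICC(2,1)."""
    r = np.asarray(r, float)
    n, k = r.shape
    grand = r.mean()
    msr = k * ((r.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((r.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = ((r - r.mean(axis=1, keepdims=True) - r.mean(axis=0, keepdims=True) + grand) ** 2).sum() / (
        (n - 1) * (k - 1)
    )
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    TABLE = np.array([[9.0, 8.0], [6.0, 5.0], [8.0, 9.0], [7.0, 6.0], [10.0, 9.0]])

    def test_identical_raters_give_one(self):
        r = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        assert icc(r).icc == pytest.approx(1.0)

    def test_matches_anova_oracle(self):
        assert icc(self.TABLE).icc == pytest.approx(icc21_oracle(self.TABLE), abs=1e-12)

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg

        n = len(self.TABLE)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile([0, 1], n),
                "score": self.TABLE.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(self.TABLE).icc == pytest.approx(icc2, abs=1e-9)

    def test_opposed_raters_negative(self):
        centered = np.array([[2.0, -2.0], [-3.0, 3.0], [1.0, -1.0], [-1.0, 1.0]])
        assert icc(centered).icc < 0

    def test_zero_between_subject_variance_undefined(self):
        r = np.array([[3.0, 5.0], [3.0, 5.0], [3.0, 5.0]])
        assert icc(r).icc is None

    def test_rater_relabeling_symmetry(self):
        assert icc(self.TABLE).icc == pytest.approx(icc(self.TABLE[:, ::-1]).icc, abs=1e-12)


class TestBlandAltman:
    def test_identical_methods(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a.copy())
        assert res.bias == 0.0 and res.loa_lower == 0.0 and res.loa_upper == 0.0

    def test_constant_offset(self):
        a = np.array([4.0, 7.0, 9.0])
        res = bland_altman(a, a - 3.0)
        assert res.bias == pytest.approx(3.0)
        assert res.loa_upper - res.loa_lower == pytest.approx(0.0, abs=1e-12)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(10, 2, 40), rng.normal(10, 2, 40)
        res = bland_altman(a, b)
        d = a - b
        assert res.bias == pytest.approx(d.mean(), abs=1e-12)
        assert res.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-12)
        assert res.loa_lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-12)
        assert np.allclose(res.plot_data["mean"], (a + b) / 2)

    def test_bias_antisymmetric_under_swap(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=15), rng.normal(size=15)
        assert bland_altman(a, b).bias == pytest.approx(-bland_altman(b, a).bias, abs=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [2.0])


class TestBhalla:
    def full(self, value=0):
        from lungdens.stats import DEFAULT_BHALLA_RUBRIC

        return {cat: min(value, hi) for cat, (lo, hi) in DEFAULT_BHALLA_RUBRIC.items()}

    def test_normal_scan_totals_zero(self):
        assert bhalla_total(BhallaRecord("p1", self.full(0))) == 0

    def test_total_monotone_in_each_subscore(self):
        base = self.full(1)
        t0 = bhalla_total(BhallaRecord("p1", base))
        for cat in base:
            bumped = dict(base)
            bumped[cat] += 1
            assert bhalla_total(BhallaRecord("p1", bumped)) >= t0

    def test_out_of_range_subscore_names_category(self):
        bad = self.full(0)
        bad["emphysema"] = 9
        with pytest.raises(ValidationError, match="emphysema"):
            bhalla_total(BhallaRecord("p1", bad))

    def test_missing_category_rejected(self):
        partial = self.full(0)
        partial.pop("number_of_bullae")
        with pytest.raises(ValidationError, match="number_of_bullae"):
            bhalla_total(BhallaRecord("p1", partial))


class TestCohortReport:
    def test_constant_column_flagged_not_fatal(self):
        import pandas as pd

        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "fev1_pct": rng.uniform(40, 110, 12),
                "fvc_pct": rng.uniform(40, 110, 12),
                "score": rng.uniform(2, 15, 12),
                "flat": np.ones(12),
            }
        )
        rep = cohort_report(df, ["score", "flat"])
        flat_rows = rep[rep["variable"] == "flat"]
        assert (flat_rows["band"] == "undefined").all()
        assert not flat_rows["defined"].any()
        assert rep[rep["variable"] == "score"]["defined"].all()
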