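"""Cohort-level statistics: Spearman correlation with interpretation
bands, paired Wilcoxon test, ICC, Bland-Altman agreement, and visual
(Bhalla-style) subscore aggregation.

Correlation magnitudes are interpreted on the conventional bands
|R| < 0.40 absent-to-weak, 0.40-0.59 moderate, 0.60-0.79 good,
>= 0.80 strong.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedStatisticError, ValidationError

BANDS = (
    (0.40, "absent to weak"),
    (0.60, "moderate"),
    (0.80, "good"),
    (np.inf, "strong"),
)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    band: str


@dataclass
class AgreementResult:
    """ICC and/or Bland-Altman agreement between two raters/methods.

    ``icc`` is None when between-subject variance is zero (undefined).
    Limits of agreement are ``bias +/- 1.96 * SD(differences)`` with the
    sample (n-1) SD, the conventional definition.
    """

    n: int
    icc: float | None = None
    bias: float | None = None
    loa_lower: float | None = None
    loa_upper: float | None = None
    plot_data: pd.DataFrame | None = None


def interpret_r(r: float) -> str:
    """Interpretation band of a correlation coefficient by |R|."""
    if not np.isfinite(r) or abs(r) > 1:
        raise ValidationError(f"correlation must satisfy |R| <= 1, got {r}")
    a = abs(r)
    for cut, label in BANDS:
        if a < cut:
            return label
    return BANDS[-1][1]  # pragma: no cover


def spearman(x, y, method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with two-sided p value.

    ``method="t"`` uses the t-distribution approximation; ``"exact"``
    enumerates all permutations (n <= 10 only) and is intended for
    validating the approximation on small inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman requires two equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValidationError(f"spearman requires n >= 3, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("spearman undefined for a constant vector")
    r, p = sps.spearmanr(x, y)
    r = float(r)
    if method == "exact":
        if n > 10:
            raise ValidationError("exact permutation p available only for n <= 10")
        p = _spearman_exact_p(x, y, r)
    elif method != "t":
        raise ValidationError(f"unknown method '{method}'")
    return CorrelationResult(r, float(p), n, interpret_r(r))


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    count = total = 0
    for perm in itertools.permutations(range(len(y))):
        rp = ry[list(perm)]
        r = np.corrcoef(rx, rp)[0, 1]
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


def wilcoxon_paired(a, b) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples (two-sided).

    Zero differences are discarded; the p value is exact when n <= 25 with
    untied nonzero |differences|, otherwise a normal approximation with
    tie correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("wilcoxon requires two equal-length 1-D vectors")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedStatisticError("wilcoxon undefined: all paired differences are zero")
    ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not ties:
        res = sps.wilcoxon(a, b, zero_method="wilcox", method="exact")
        return float(res.statistic), float(res.pvalue)
    if n <= 15:  # ties present: enumerate the 2^n sign assignments with midranks
        ranks = sps.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        total = float(ranks.sum())
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w_all = signs @ ranks
        # two-sided: as-or-more-extreme distance from the null center S/2
        p = float(np.mean(np.abs(w_all - total / 2) >= np.abs(w_plus - total / 2) - 1e-12))
        return min(w_plus, total - w_plus), p
    res = sps.wilcoxon(a, b, zero_method="wilcox", method="approx")
    return float(res.statistic), float(res.pvalue)


def icc(ratings) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n_subjects, n_raters) table.  Computed from the
    two-way ANOVA mean squares::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns ``icc=None`` (undefined) when between-subject variance is zero.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise ValidationError("icc requires an (n_subjects, n_raters>=2) table")
    if np.any(~np.isfinite(r)):
        raise ValidationError("icc requires complete ratings (no missing cells)")
    n, k = r.shape
    if n < 3:
        raise ValidationError(f"icc requires n >= 3 subjects, got {n}")
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((r - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    # undefined when there is no between-subject signal to attribute:
    # degenerate tables (constant rows) have MSR = MSE = 0
    if (msr == 0.0 and mse == 0.0) or denom == 0.0:
        return AgreementResult(n=n, icc=None)
    return AgreementResult(n=n, icc=float((msr - mse) / denom))


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman agreement: bias = mean(a-b), limits = bias +/- 1.96 SD.

    The returned ``plot_data`` holds the per-pair mean and difference for
    the conventional agreement plot.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("bland_altman requires two equal-length 1-D vectors")
    n = len(a)
    if n < 2:
        raise ValidationError(f"bland_altman requires n >= 2 pairs, got {n}")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    plot = pd.DataFrame({"mean": (a + b) / 2.0, "difference": d})
    return AgreementResult(
        n=n, bias=bias, loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd, plot_data=plot
    )


# ---------------------------------------------------------------------------
# Visual (Bhalla-style) subscore aggregation.  The category definitions and
# admissible ranges live in configuration, not code: the rubric is external
# and sites may use modified variants.

DEFAULT_BHALLA_RUBRIC: dict[str, tuple[int, int]] = {
    "severity_of_bronchiectasis": (0, 3),
    "peribronchial_thickening": (0, 3),
    "extent_of_bronchiectasis": (0, 3),
    "extent_of_mucus_plugging": (0, 3),
    "sacculations_or_abscesses": (0, 3),
    "generations_of_bronchial_divisions_involved": (0, 3),
    "number_of_bullae": (0, 3),
    "emphysema": (0, 2),
    "collapse_or_consolidation": (0, 2),
}


@dataclass
class BhallaRecord:
    """One patient's nine visual category subscores."""

    patient_id: str
    subscores: dict[str, int]
    rubric: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(DEFAULT_BHALLA_RUBRIC))


def bhalla_total(record: BhallaRecord) -> int:
    """Total visual score: the sum of the category subscores.

    With this severity-increasing convention 0 is a normal scan and the
    total is monotone non-decreasing in every subscore.  (The classic
    offset-minus-sum presentation is an affine relabeling and changes no
    rank-based statistic.)
    """
    if set(record.subscores) != set(record.rubric):
        missing = set(record.rubric) - set(record.subscores)
        extra = set(record.subscores) - set(record.rubric)
        raise ValidationError(f"subscores do not match rubric categories (missing {sorted(missing)}, unexpected {sorted(extra)})")
    total = 0
    for cat, val in record.subscores.items():
        lo, hi = record.rubric[cat]
        if not isinstance(val, (int, np.integer)) or not (lo <= val <= hi):
            raise ValidationError(f"subscore '{cat}' = {val} outside admissible range [{lo}, {hi}]")
        total += int(val)
    return total


# ---------------------------------------------------------------------------
# Cohort report: the correlation matrix of histogram characteristics and
# density scores against spirometry, plus regional and interobserver blocks.


def cohort_report(
    table: pd.DataFrame,
    value_columns: list[str],
    spirometry_columns: tuple[str, str] = ("fev1_pct", "fvc_pct"),
) -> pd.DataFrame:
    """Spearman R, p and band of each value column against each spirometry
    column.  Constant columns are reported with an ``undefined`` flag
    rather than aborting the run."""
    if len(table) < 3:
        raise ValidationError(f"cohort report requires >= 3 patients, got {len(table)}")
    rows = []
    for col in value_columns:
        for spiro in spirometry_columns:
            sub = table[[col, spiro]].dropna()
            try:
                res = spearman(sub[col].to_numpy(), sub[spiro].to_numpy())
                rows.append(
                    {"variable": col, "against": spiro, "r": res.r, "p": res.p,
                     "n": res.n, "band": res.band, "defined": True}
                )
            except (UndefinedStatisticError, ValidationError):
                rows.append(
                    {"variable": col, "against": spiro, "r": np.nan, "p": np.nan,
                     "n": len(sub), "band": "undefined", "defined": False}
                )
    return pd.DataFrame(rows)
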