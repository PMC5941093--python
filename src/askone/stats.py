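"""Descriptive and inferential statistics for screened cohorts.

Covers the 2x2 contingency machinery used to compare risk rates between
children with and without a family history of autism (odds ratios with
Woolf log-interval CIs, uncorrected Pearson chi-square), Spearman
correlations with a Bonferroni multiplicity threshold, and the two-way
random-effects intraclass correlation for agreement between clinical
raters.

Formula choices are deliberately pinned: the published group counts only
reproduce the printed statistics with the *uncorrected* chi-square (the
Yates-corrected value for the strongest row is ~8.3, not 9.6) and with the
Woolf (log) interval rather than an exact interval.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "odds_ratio_ci",
    "chi_square_2x2",
    "chi_square_2x2_yates",
    "spearman",
    "bonferroni_threshold",
    "icc_agreement",
    "TABLE1_MEASURES",
    "table1_report",
]


class ContingencyTable2x2(NamedTuple):
    """Counts: a = exposed & at-risk, b = exposed & not, c = unexposed &
    at-risk, d = unexposed & not."""

    a: int
    b: int
    c: int
    d: int

    def validate(self) -> "ContingencyTable2x2":
        if any(x < 0 for x in self):
            raise ValueError(f"counts must be non-negative, got {tuple(self)}")
        if sum(self) < 1:
            raise ValueError("table must contain at least one observation")
        return self


class OddsRatioResult(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool


def odds_ratio_ci(t: ContingencyTable2x2, alpha: float = 0.05) -> OddsRatioResult:
    """Odds ratio ad/(bc) with the Woolf log-interval CI.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction applied to
    all four cells, flagged in the result.
    """
    t = ContingencyTable2x2(*t).validate()
    a, b, c, d = (float(x) for x in t)
    corrected = 0 in (t.a, t.b, t.c, t.d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    return OddsRatioResult(
        odds_ratio=float(or_),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        haldane_corrected=corrected,
    )


def chi_square_2x2(t: ContingencyTable2x2) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (statistic, df=1, p)."""
    t = ContingencyTable2x2(*t).validate()
    table = np.array([[t.a, t.b], [t.c, t.d]], dtype=np.float64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a marginal total is zero")
    res = scipy.stats.chi2_contingency(table, correction=False)
    return float(res.statistic), 1, float(res.pvalue)


def chi_square_2x2_yates(t: ContingencyTable2x2) -> tuple[float, int, float]:
    """Yates-corrected variant, retained to document the formula pinning."""
    t = ContingencyTable2x2(*t).validate()
    table = np.array([[t.a, t.b], [t.c, t.d]], dtype=np.float64)
    res = scipy.stats.chi2_contingency(table, correction=True)
    return float(res.statistic), 1, float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Midrank Spearman correlation with large-sample p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def icc_agreement(
    ratings, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Two-way random, absolute-agreement, single-rater ICC with F-based CI.

    ``ratings`` is a (n_raters, n_subjects) matrix with no missing cells.
    Returns (icc, ci_low, ci_high). Zero between-subject variance yields
    ICC 0 with a warning.
    """
    R = np.asarray(ratings, dtype=np.float64)
    if R.ndim != 2:
        raise ValueError("ratings must be a 2-d raters x subjects matrix")
    k, n = R.shape
    if k < 2 or n < 5:
        raise ValueError("need at least 2 raters and 5 subjects")
    if np.isnan(R).any():
        raise ValueError("ratings must have no missing cells")

    X = R.T  # subjects x raters
    grand = X.mean()
    subj_means = X.mean(axis=1)
    rater_means = X.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)  # between-subject mean square
    msc = ss_rater / (k - 1)  # between-rater mean square
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= mse or denom <= 0:
        warnings.warn(
            "zero (or negative) between-subject variance; ICC set to 0",
            stacklevel=2,
        )
        return 0.0, 0.0, 0.0
    icc = (msr - mse) / denom

    if mse <= 1e-300:  # perfect within-subject agreement: degenerate CI
        return float(icc), float(icc), float(icc)

    # F-based interval (two-way random, absolute agreement, single rater).
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (
        k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
    ) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (
        n * (1 + (k - 1) * icc) - k * icc
    ) ** 2
    v = vn / vd
    f_u = scipy.stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = scipy.stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_u * mse) / (
        f_u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_l * msr
    )
    return float(icc), float(lower), float(upper)


#: (column name, report label) for the eight per-measure risk flags.
TABLE1_MEASURES = (
    ("mchat_r_risk", "M-CHAT-R medium + high risk"),
    ("mchat_rf_risk", "M-CHAT-R/F risk (count fail >= 2)"),
    ("asq_global_risk", "ASQ risk"),
    ("asq_communication_refer", "ASQ Communication"),
    ("asq_personal_social_refer", "ASQ Personal-Social"),
    ("asq_gross_motor_refer", "ASQ Gross motor"),
    ("asq_fine_motor_refer", "ASQ Fine motor"),
    ("asq_problem_solving_refer", "ASQ Problem solving"),
)


def table1_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-measure risk rates stratified by family history, with OR/CI/chi2.

    ``cohort`` needs a boolean ``family_asd`` column plus the eight measure
    columns of :data:`TABLE1_MEASURES`. Cohorts without both family-history
    groups get NaN inferential statistics and a flag instead of an error.
    """
    fam = cohort["family_asd"].astype(bool).to_numpy()
    n_total, n_fam, n_nofam = len(cohort), int(fam.sum()), int((~fam).sum())
    rows = []
    for col, label in TABLE1_MEASURES:
        risk = cohort[col].astype(bool).to_numpy()
        a = int((risk & fam).sum())  # family & at-risk
        b = int((~risk & fam).sum())
        c = int((risk & ~fam).sum())
        d = int((~risk & ~fam).sum())
        row = {
            "measure": label,
            "n_total": int(risk.sum()),
            "pct_total": round(100 * risk.sum() / n_total, 1) if n_total else np.nan,
            "n_no_family": c,
            "pct_no_family": round(100 * c / n_nofam, 1) if n_nofam else np.nan,
            "n_family": a,
            "pct_family": round(100 * a / n_fam, 1) if n_fam else np.nan,
        }
        if n_fam == 0 or n_nofam == 0:
            row.update(
                odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                chi2=np.nan, df=1, p=np.nan, undefined=True,
            )
        else:
            orr = odds_ratio_ci(ContingencyTable2x2(a, b, c, d))
            stat, df, p = chi_square_2x2(ContingencyTable2x2(a, b, c, d))
            row.update(
                odds_ratio=orr.odds_ratio,
                ci_low=orr.ci_low,
                ci_high=orr.ci_high,
                chi2=stat,
                df=df,
                p=p,
                undefined=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)
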