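"""Interobserver reproducibility statistics: ICC, COV, agreement labels.

Reliability of observer-dependent coregistration is quantified with the
single-rater intraclass correlation under the two-way mixed-effects model
(subjects random, observers fixed), in both its absolute-agreement (ICC_A,
McGraw & Wong ICC(A,1)) and consistency (ICC_C, ICC(C,1)) forms:

    ICC_C = (MS_R - MS_E) / (MS_R + (k-1) MS_E)
    ICC_A = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

with MS_R, MS_C, MS_E the subject, observer and residual mean squares of the
two-way decomposition of an n-subjects x k-observers table. Reproducibility is
summarised as a coefficient of variation: the pooled SD of all pairwise
between-observer differences divided by the grand mean, assuming homogeneous
within-subject variability.

Shapiro-Wilk, paired t and two-way ANOVA with Bonferroni correction are
standard tests exposed as thin pass-throughs over scipy/statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("ratpet")

__all__ = [
    "RaterTable",
    "ICCResult",
    "icc_two_way_mixed",
    "between_observer_cov",
    "agreement_label",
    "shapiro_wilk",
    "paired_ttest",
    "two_way_anova",
    "bonferroni_pairwise",
]


@dataclass
class RaterTable:
    """Subjects x observers measurement matrix (listwise complete)."""

    values: np.ndarray  # (n_subjects, k_observers)
    subjects: list | None = None
    observers: list | None = None
    region: str | None = None
    time_min: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("rater table must be 2-D (subjects x observers)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 observers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rater table must be complete and finite")
        if self.subjects is None:
            self.subjects = list(range(n))
        if self.observers is None:
            self.observers = list(range(k))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject="subject", observer="observer", value="value"):
        wide = df.pivot(index=subject, columns=observer, values=value)
        if wide.isna().any().any():
            raise ValueError("rater table must be listwise complete")
        return cls(wide.to_numpy(), list(wide.index), list(wide.columns))


@dataclass
class ICCResult:
    icc_a: float
    icc_c: float
    ci_a: tuple
    ci_c: tuple
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int
    defined: bool = True


def _mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_error = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(ms_rows), float(ms_cols), float(ms_error)


def icc_two_way_mixed(table: RaterTable, alpha: float = 0.05) -> ICCResult:
    """Single-rater two-way mixed-effects ICC for absolute agreement and
    consistency, with F-based 95% confidence intervals (McGraw & Wong 1996).

    A table with zero total variance (all cells equal) carries no agreement
    information; the result is marked undefined rather than propagating NaN.
    """
    x = table.values
    n, k = x.shape
    ms_r, ms_c, ms_e = _mean_squares(x)

    if np.allclose(x, x.flat[0]):
        nan = float("nan")
        return ICCResult(nan, nan, (nan, nan), (nan, nan), ms_r, ms_c, ms_e, n, k, defined=False)

    icc_c = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e) if (ms_r + (k - 1) * ms_e) > 0 else float("nan")
    denom_a = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    icc_a = (ms_r - ms_e) / denom_a if denom_a > 0 else float("nan")

    # --- consistency CI: exact F bounds ---
    if ms_e > 0:
        f_obs = ms_r / ms_e
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        ci_c = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    else:
        ci_c = (icc_c, icc_c)

    # --- absolute-agreement CI: Satterthwaite approximation ---
    if ms_e > 0 and np.isfinite(icc_a) and icc_a < 1:
        a = (k * icc_a) / (n * (1 - icc_a))
        b = 1 + (k * icc_a * (n - 1)) / (n * (1 - icc_a))
        num = (a * ms_c + b * ms_e) ** 2
        den = (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else (n - 1) * (k - 1)
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (ms_r - f1 * ms_e) / (f1 * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r)
        upper = n * (f2 * ms_r - ms_e) / (k * ms_c + (k * n - k - n) * ms_e + n * f2 * ms_r)
        ci_a = (lower, upper)
    else:
        ci_a = (icc_a, icc_a)

    clip = lambda c: tuple(float(np.clip(v, -1.0, 1.0)) for v in c)
    return ICCResult(float(icc_a), float(icc_c), clip(ci_a), clip(ci_c), ms_r, ms_c, ms_e, n, k)


def between_observer_cov(table: RaterTable, normalizer: str = "grand_mean") -> float:
    """Between-observer coefficient of variation (percent).

    All pairwise observer differences are formed per subject; their pooled
    sample SD is divided by the grand mean (the within-subject variability is
    assumed homogeneous across subjects). Returns NaN (undefined) when the
    grand mean is zero.
    """
    if normalizer != "grand_mean":
        raise ValueError("only the 'grand_mean' normalizer is implemented")
    x = table.values
    n, k = x.shape
    diffs = [x[:, i] - x[:, j] for i in range(k) for j in range(i + 1, k)]
    pooled = np.concatenate(diffs)
    grand = x.mean()
    if grand == 0:
        logger.warning("grand mean is zero: COV undefined")
        return float("nan")
    sd = pooled.std(ddof=1)
    return float(sd / grand * 100.0)


_AGREEMENT_BINS = [
    (0.40, "poor to fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
]


def agreement_label(icc: float) -> str:
    """Verbal agreement category for an ICC (upper bin edges inclusive)."""
    if not -1.0 <= icc <= 1.0:
        raise ValueError(f"ICC must be in [-1, 1], got {icc}")
    for upper, label in _AGREEMENT_BINS:
        if icc <= upper:
            return label
    return _AGREEMENT_BINS[-1][1]  # pragma: no cover


# ---------------------------------------------------------------------------
# Pass-through wrappers over established routines
# ---------------------------------------------------------------------------


def shapiro_wilk(values):
    """Shapiro-Wilk normality test; returns (W, p)."""
    res = sps.shapiro(np.asarray(values, dtype=float))
    return float(res.statistic), float(res.pvalue)


def paired_ttest(a, b):
    """Two-tailed paired Student's t-test; returns (t, p)."""
    res = sps.ttest_rel(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    return float(res.statistic), float(res.pvalue)


def two_way_anova(df: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA (type II) via statsmodels OLS; returns the ANOVA table."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) + C(_b)", data=data).fit()
    return sm.stats.anova_lm(model, typ=2)


def bonferroni_pairwise(groups: dict) -> pd.DataFrame:
    """All pairwise paired t-tests with Bonferroni-adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            t, p = paired_ttest(groups[a], groups[b])
            rows.append({"a": a, "b": b, "t": t, "p_raw": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bonferroni"] = multipletests(out["p_raw"], method="bonferroni")[1]
    return out
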