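"""Outcome statistics: NDS scoring, group tests, survival, prognosis.

Implements the statistical layer that links quantitative EEG recovery
metrics to neurological outcome in a two-arm resuscitation experiment:

* the neurological deficit score (NDS), a seven-category scale from 0
  (no deficit) to 500 (brain death);
* two-sample Welch t-tests, from raw samples or from printed mean/SD/n
  summaries (the unequal-variance form with Satterthwaite degrees of
  freedom reproduces the study's printed p-values, including the
  zero-variance group case where df collapses to n−1 of the other group);
* Fisher's exact test for survival proportions (two-sided by summing all
  hypergeometric tables no more probable than the observed one);
* Spearman correlation and single-predictor logistic regression for
  prognosis;
* Kaplan–Meier curves with the log-rank test, censoring at 96 h;
* two-way (group × time) ANOVA with unadjusted per-time Welch post hoc
  comparisons.

No multiple-testing adjustment is applied by default; Holm-adjusted
p-values are available via :func:`holm_adjust` for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NDS_CATEGORIES",
    "NDSRecord",
    "nds_total",
    "SurvivalRecord",
    "TestResult",
    "welch_t_summary",
    "welch_t_raw",
    "fisher_exact_2x2",
    "spearman",
    "LogisticFit",
    "logistic_single",
    "KMResult",
    "km_logrank",
    "twoway_anova_posthoc",
    "holm_adjust",
]

#: Allowed scores per NDS category (ascending deficit).
NDS_CATEGORIES: dict[str, tuple[int, ...]] = {
    "consciousness": (0, 50, 100),
    "respiration": (0, 50, 100),
    "cornea_reflex": (0, 20, 40),
    "cranial_gag_reflex": (0, 15, 30),
    "auditory_reflex": (0, 15, 30),
    "motor_sensory": (0, 50, 100),
    "behavior": (0, 50, 100),
}


@dataclass
class NDSRecord:
    """One day's neurological deficit assessment (seven categories)."""

    consciousness: int
    respiration: int
    cornea_reflex: int
    cranial_gag_reflex: int
    auditory_reflex: int
    motor_sensory: int
    behavior: int
    day: int = 1

    def __post_init__(self) -> None:
        for cat, allowed in NDS_CATEGORIES.items():
            val = getattr(self, cat)
            if val not in allowed:
                raise ValueError(
                    f"NDS category '{cat}' must be one of {allowed}, got {val}"
                )
        if not 1 <= self.day <= 4:
            raise ValueError("assessment day must be 1–4")


def nds_total(record: NDSRecord) -> int:
    """Total deficit score: sum of the seven categories, 0 (intact) – 500."""
    return sum(getattr(record, cat) for cat in NDS_CATEGORIES)


@dataclass
class SurvivalRecord:
    """Time-to-death over the 96 h observation window."""

    time_hr: float
    event: int  # 1 = death observed, 0 = censored at 96 h

    def __post_init__(self) -> None:
        if self.time_hr <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.event == 0 and self.time_hr != 96.0:
            raise ValueError("censored records are censored at 96 h")


@dataclass
class TestResult:
    """Generic two-sample test result."""

    statistic: float
    df: float
    p: float
    direction: int = 0  # sign of (group1 − group2) effect

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def welch_t_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TestResult:
    """Welch's unequal-variance t-test from group mean / SD / n.

    t = (m1 − m2) / sqrt(s1²/n1 + s2²/n2) with Welch–Satterthwaite df.
    When one SD is zero the df reduces to n−1 of the varying group; when
    both SDs are zero, p is 1 for equal means (0 with a warning otherwise).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be nonnegative")
    direction = int(np.sign(m1 - m2))
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return TestResult(0.0, float(n1 + n2 - 2), 1.0, 0)
        warnings.warn(
            "both groups have zero variance with unequal means; p = 0",
            stacklevel=2,
        )
        return TestResult(float("inf"), float(n1 + n2 - 2), 0.0, direction)
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    denom = (v1**2 / (n1 - 1) if s1 > 0 else 0.0) + (
        v2**2 / (n2 - 1) if s2 > 0 else 0.0
    )
    df = (v1 + v2) ** 2 / denom
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), direction)


def welch_t_raw(x, y) -> TestResult:
    """Welch's t-test from raw samples (identical to the summary form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2 finite values")
    return welch_t_summary(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test of the table [[a, b], [c, d]].

    Two-sided p sums the hypergeometric probabilities of every table with
    the observed margins that is no more probable than the observed one.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        return TestResult(float("nan"), float("nan"), 1.0, 0)
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    direction = int(np.sign(a * d - b * c))
    return TestResult(float(odds), float("nan"), float(p), direction)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties), with t-approximation p.

    Returns ``(rho, p)``; both NaN when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class LogisticFit:
    """Single-predictor logistic regression fit."""

    intercept: float
    slope: float
    slope_p: float
    converged: bool
    separated: bool

    def predict(self, x) -> np.ndarray:
        """Fitted probability curve P(outcome = 1 | x)."""
        z = self.intercept + self.slope * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def logistic_single(predictor, outcome) -> LogisticFit:
    """Maximum-likelihood logistic regression with one predictor.

    The Wald test on the slope gives the p-value. Complete separation is
    detected (fitted probabilities all ~0/1 at the observed outcomes, or a
    non-converged diverging fit) and flagged instead of silently returning a
    divergent estimate.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(x) != len(y) or len(x) < 6:
        raise ValueError("need paired samples with n >= 6")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("outcome must contain both classes coded 0/1")

    design = sm.add_constant(x)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:  # statsmodels raises on hopeless separation
            return LogisticFit(np.nan, np.nan, np.nan, False, True)
    separated = any(
        issubclass(w.category, PerfectSeparationWarning) for w in caught
    )
    converged = bool(fit.mle_retvals.get("converged", False))
    prob = fit.predict(design)
    eps = 1e-8
    if np.all((prob > 1 - eps) == (y == 1)) and np.all((prob < eps) == (y == 0)):
        separated = True
    return LogisticFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        slope_p=float(fit.pvalues[1]),
        converged=converged,
        separated=separated,
    )


@dataclass
class KMResult:
    """Kaplan–Meier curves for two groups plus the log-rank test."""

    curves: dict[str, pd.DataFrame]  # group → columns (time_hr, survival)
    logrank_stat: float
    p: float

    def survival_at(self, group: str, time_hr: float) -> float:
        """Step-function value of the product-limit estimate at ``time_hr``."""
        df = self.curves[group]
        mask = df["time_hr"] <= time_hr + 1e-9
        return float(df.loc[mask, "survival"].iloc[-1]) if mask.any() else 1.0


def km_logrank(
    group1: list[SurvivalRecord],
    group2: list[SurvivalRecord],
    names: tuple[str, str] = ("group1", "group2"),
) -> KMResult:
    """Product-limit survival estimates and the two-group log-rank test.

    Day-resolution ties are handled by the standard tied-risk-set log-rank
    formulation. With no events in either group the log-rank statistic is
    undefined and reported as NaN.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    if not group1 or not group2:
        raise ValueError("each group needs at least one subject")
    curves = {}
    datasets = []
    for name, grp in zip(names, (group1, group2)):
        t = np.array([r.time_hr for r in grp])
        e = np.array([r.event for r in grp])
        datasets.append((t, e))
        kmf = KaplanMeierFitter()
        kmf.fit(t, e)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time_hr", "survival"]
        curves[name] = sf
    (t1, e1), (t2, e2) = datasets
    if e1.sum() + e2.sum() == 0:
        return KMResult(curves, float("nan"), float("nan"))
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return KMResult(curves, float(res.test_statistic), float(res.p_value))


def twoway_anova_posthoc(
    data: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    time: str = "time",
) -> tuple[pd.DataFrame, dict[object, TestResult]]:
    """Two-way (group × time) ANOVA plus per-time Welch post hoc tests.

    Type-II sums of squares on an OLS fit of ``value ~ C(group) * C(time)``.
    Post hoc comparisons are unadjusted two-sample Welch tests at each time
    point; time points where either group is empty are excluded with a
    warning. Returns ``(anova_table, {time: TestResult})``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[[value, group, time]].dropna().copy()
    df.columns = ["value", "group", "time"]
    if df["group"].nunique() != 2:
        raise ValueError("exactly two groups required")
    model = smf.ols("value ~ C(group) * C(time)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    g1, g2 = sorted(df["group"].unique())
    posthoc: dict[object, TestResult] = {}
    for t, sub in df.groupby("time"):
        x = sub.loc[sub["group"] == g1, "value"].to_numpy()
        y = sub.loc[sub["group"] == g2, "value"].to_numpy()
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"time point {t!r} excluded (fewer than 2 per group)")
            continue
        if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
            posthoc[t] = TestResult(0.0, float(len(x) + len(y) - 2), 1.0, 0)
        else:
            posthoc[t] = welch_t_raw(x, y)
    return table, posthoc


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values (off the default analysis path)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]
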