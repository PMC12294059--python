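"""Group-comparison statistics.

Two-group comparisons follow a normality gate: Shapiro-Wilk per group,
Welch's t-test when both groups look normal, Mann-Whitney U otherwise.
Categorical contrasts use Pearson chi-square (Yates-corrected for 2x2
tables). Effect sizes are pooled-SD Cohen's d with a normal-theory 95%
CI, computable from printed summary statistics so published tables can
be checked without raw data. A MANOVA across the 12 visual atrophy
ratings contrasts PD and control multivariate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import ATROPHY_COLUMNS

_Z975 = sps.norm.ppf(0.975)


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    group_summaries: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")

    def to_dict(self) -> dict:
        d = {"test": self.test_name, "statistic": self.statistic,
             "df": self.df, "p_value": self.p_value}
        d.update(self.extras)
        return d


@dataclass
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    method: str = "cohen_pooled"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.d <= self.ci_high):
            raise ValueError("d outside its confidence interval")


def _summary(x) -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    if isinstance(x, (tuple, list)) and len(x) == 3:
        return GroupSummary(int(x[0]), float(x[1]), float(x[2]))
    arr = np.asarray(x, dtype=float)
    return GroupSummary(len(arr), float(arr.mean()), float(arr.std(ddof=1)))


def shapiro_gate(*samples, alpha: float = 0.05) -> str:
    """Choose the test family from per-group Shapiro-Wilk normality.

    Returns ``"nonparametric"`` if any group rejects normality at
    ``alpha`` (or is constant, for which normality is undefined and the
    rank test is the safe default — documented choice), else
    ``"parametric"``. Each sample needs n >= 3.
    """
    for x in samples:
        arr = np.asarray(x, dtype=float)
        if len(arr) < 3:
            raise ValueError("Shapiro-Wilk requires n >= 3")
        if np.ptp(arr) == 0:
            return "nonparametric"
        if sps.shapiro(arr).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance t-test with Satterthwaite df.

    Accepts raw samples or ``(n, mean, sd)`` summaries, so statistics
    printed in a table can be recomputed exactly.
    """
    sa, sb = _summary(a), _summary(b)
    if sa.n < 2 or sb.n < 2:
        raise ValueError("welch_t requires n >= 2 per group")
    va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
    if va + vb == 0:
        raise ValueError("both groups have zero variance")
    t = (sa.mean - sb.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult("welch_t", float(t), float(p), df=float(df),
                      group_summaries={"a": sa, "b": sb})


def mann_whitney_u(a, b) -> TestResult:
    """Mann-Whitney U with tie-corrected normal approximation (two-sided).

    The reported U is the number of (a_i > b_j) pairs plus half the
    ties, i.e. the U statistic of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue),
                      df=None,
                      group_summaries={"a": _summary(a), "b": _summary(b)})


def chi_square(table, yates: bool | None = None) -> TestResult:
    """Pearson chi-square test of independence on a counts table.

    ``yates=None`` applies the continuity correction exactly when the
    table is 2x2 (the convention under which the published 2x2 sex
    contrast reproduces); pass an explicit flag to override.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (tab < 0).any() or np.any(tab % 1 != 0):
        raise ValueError("counts must be nonnegative integers")
    if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
        raise ValueError("table has an all-zero row or column")
    if yates is None:
        yates = tab.shape == (2, 2)
    res = sps.chi2_contingency(tab, correction=yates)
    return TestResult("chi_square", float(res.statistic), float(res.pvalue),
                      df=int(res.dof), extras={"yates": bool(yates)})


def cohens_d(a, b, hedges: bool = False, conf: float = 0.95) -> EffectSize:
    """Pooled-SD Cohen's d with a normal-approximation CI.

    ``s_pooled^2 = ((n_a-1) sd_a^2 + (n_b-1) sd_b^2) / (n_a+n_b-2)`` and
    ``SE(d) = sqrt((n_a+n_b)/(n_a n_b) + d^2 / (2 (n_a+n_b)))``. Hedges'
    small-sample correction is available but off by default.
    """
    sa, sb = _summary(a), _summary(b)
    if sa.n < 2 or sb.n < 2:
        raise ValueError("cohens_d requires n >= 2 per group")
    n = sa.n + sb.n
    sp2 = ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / (n - 2)
    if sp2 <= 0:
        raise ValueError("degenerate variance in both groups")
    d = (sa.mean - sb.mean) / np.sqrt(sp2)
    method = "cohen_pooled"
    if hedges:
        d *= 1 - 3 / (4 * n - 9)
        method = "hedges_g"
    se = np.sqrt(n / (sa.n * sb.n) + d**2 / (2 * n))
    z = sps.norm.ppf(0.5 + conf / 2)
    return EffectSize(float(d), float(d - z * se), float(d + z * se), method)


def compare_groups(a, b, label: str = "") -> tuple[TestResult, EffectSize]:
    """Normality-gated two-group comparison: Welch t if both groups pass
    Shapiro-Wilk, Mann-Whitney U otherwise; Cohen's d alongside."""
    gate = shapiro_gate(a, b)
    res = welch_t(a, b) if gate == "parametric" else mann_whitney_u(a, b)
    res.extras["variable"] = label
    res.extras["gate"] = gate
    return res, cohens_d(a, b)


def manova_ratings(groups, ratings, statistic: str = "wilks",
                   adjust: str = "bonferroni") -> TestResult:
    """MANOVA contrasting group multivariate means over rating columns.

    Reports Wilks' lambda (or Pillai's trace) with its F approximation,
    plus per-feature univariate follow-up F tests corrected for multiple
    comparisons.
    """
    from statsmodels.multivariate.manova import MANOVA

    from .correlations import adjust_pvalues

    y = np.asarray(ratings, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if y.shape[0] <= y.shape[1] + len(levels):
        raise ValueError("too few observations for the number of features")
    codes = pd.Categorical(groups).codes
    if y.shape[1] == 1:
        # MANOVA on one variable is one-way ANOVA: Wilks' lambda is
        # SS_within / SS_total with F = ((1-L)/L) * (df_e / df_h)
        samples = [y[codes == c, 0] for c in np.unique(codes)]
        grand = y[:, 0].mean()
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        ss_total = ((y[:, 0] - grand) ** 2).sum()
        lam = ss_within / ss_total
        df_h, df_e = len(samples) - 1, len(y) - len(samples)
        fval = (1 - lam) / lam * df_e / df_h
        p = float(sps.f.sf(fval, df_h, df_e))
        stat = float(lam if statistic == "wilks" else 1 - lam)
        return TestResult(
            f"manova_{statistic}", stat, p, df=(float(df_h), float(df_e)),
            extras={"F": float(fval), "followup_F": [float(fval)],
                    "followup_p_raw": [p], "followup_p_adjusted": [p]},
        )
    try:
        mv = MANOVA(endog=y, exog=np.column_stack(
            [np.ones(len(codes)), pd.get_dummies(codes).to_numpy(float)[:, 1:]]))
        tab = mv.mv_test(
            hypotheses=[("group", np.eye(1 + len(levels) - 1)[1:], None)]
        ).results["group"]["stat"]
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise ValueError(
            "singular pooled covariance; consider shrinkage or fewer features"
        ) from err
    row = "Wilks' lambda" if statistic == "wilks" else "Pillai's trace"
    stat = float(tab.loc[row, "Value"])
    fval = float(tab.loc[row, "F Value"])
    df = (float(tab.loc[row, "Num DF"]), float(tab.loc[row, "Den DF"]))
    p = float(tab.loc[row, "Pr > F"])
    # Univariate follow-ups: one-way ANOVA F per rating column.
    praw, fstats = [], []
    for j in range(y.shape[1]):
        samples = [y[codes == c, j] for c in np.unique(codes)]
        f = sps.f_oneway(*samples)
        fstats.append(float(f.statistic))
        praw.append(float(f.pvalue))
    padj = adjust_pvalues(np.array(praw), method=adjust)
    return TestResult(
        f"manova_{statistic}", stat, p, df=df,
        extras={
            "F": fval,
            "followup_F": fstats,
            "followup_p_raw": praw,
            "followup_p_adjusted": list(map(float, padj)),
        },
    )


def table1_report(table) -> pd.DataFrame:
    """Demographics/screens group-comparison report for a cohort.

    One row per variable: gate outcome, test statistic, df, p, Cohen's d
    with CI for continuous variables; chi-square rows for sex,
    handedness and education.
    """
    from .cohort import SCREEN_TESTS

    pd_rows, ctl = table.pd_rows(), table.control_rows()
    rows = []
    for var in ("age", *SCREEN_TESTS):
        a = pd_rows[var].dropna().to_numpy()
        b = ctl[var].dropna().to_numpy()
        res, eff = compare_groups(a, b, label=var)
        rows.append({
            "variable": var, "test": res.test_name,
            "statistic": res.statistic, "df": res.df, "p_value": res.p_value,
            "pd_mean": a.mean(), "pd_sd": a.std(ddof=1),
            "control_mean": b.mean(), "control_sd": b.std(ddof=1),
            "cohens_d": eff.d, "d_ci_low": eff.ci_low, "d_ci_high": eff.ci_high,
        })
    for var in ("sex", "handedness", "education"):
        ct = pd.crosstab(table.data["group"], table.data[var])
        ct = ct.loc[:, ct.sum(axis=0) > 0]
        res = chi_square(ct.to_numpy())
        rows.append({"variable": var, "test": res.test_name,
                     "statistic": res.statistic, "df": res.df,
                     "p_value": res.p_value})
    return pd.DataFrame(rows)
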