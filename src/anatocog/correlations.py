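"""Correlation and regression analyses.

Pearson correlations between individual neuropsychological tests and the
PD-CRS composite scores (pairwise-complete, Bonferroni- or FDR-
corrected), partial correlations adjusted for age and education
(residual-on-residual), and standardized OLS regressions with automatic
residual diagnostics (Shapiro-Wilk normality, Levene homoscedasticity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationResult:
    x: str
    y: str
    r: float
    p_raw: float
    n: int
    method: str = "pearson"
    covariates: list = field(default_factory=list)
    p_adjusted: float | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "x": self.x, "y": self.y, "r": self.r, "n": self.n,
            "p_raw": self.p_raw, "p_adjusted": self.p_adjusted,
            "method": self.method, "covariates": ";".join(self.covariates),
            "note": self.note,
        }


@dataclass
class RegressionResult:
    outcome: str
    predictors: list
    standardized_betas: dict
    p_values: dict
    r_squared: float
    residual_shapiro_p: float
    residual_levene_p: float


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-comparison adjustment.

    ``bonferroni``: min(1, m*p). ``bh_fdr``: Benjamini-Hochberg step-up
    with enforced monotonicity. ``none`` returns the input.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0 or method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "bh_fdr":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(1.0, ranked)
        return out
    raise ValueError(f"unknown method {method!r}")


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        raise ValueError("pairwise-complete n < 3")
    xm, ym = x[mask], y[mask]
    if np.ptp(xm) == 0 or np.ptp(ym) == 0:
        raise ValueError("constant column")
    r, p = sps.pearsonr(xm, ym)
    return float(r), float(p), n


def pearson_matrix(tests, composites, adjust: str = "bonferroni") -> list[CorrelationResult]:
    """Pearson r of every test against every composite score.

    Both arguments are DataFrames (or FeatureMatrix, via ``to_frame``)
    sharing a participant index; each pair uses its own pairwise-
    complete cases, so n can vary across rows as in published tables.
    Constant or too-sparse pairs are reported with an explanatory note
    instead of an r. Adjustment spans all computed pairs.
    """
    tests = tests.to_frame() if hasattr(tests, "to_frame") else tests
    composites = (composites.to_frame()
                  if hasattr(composites, "to_frame") else composites)
    results: list[CorrelationResult] = []
    for tcol in tests.columns:
        for ccol in composites.columns:
            x = tests[tcol].to_numpy(dtype=float)
            y = composites.reindex(tests.index)[ccol].to_numpy(dtype=float)
            try:
                r, p, n = _pearson(x, y)
                results.append(CorrelationResult(tcol, ccol, r, p, n))
            except ValueError as err:
                results.append(CorrelationResult(
                    tcol, ccol, np.nan, np.nan, 0, note=str(err)))
    valid = [res for res in results if not np.isnan(res.p_raw)]
    padj = adjust_pvalues([res.p_raw for res in valid], method=adjust)
    for res, pa in zip(valid, padj):
        res.p_adjusted = float(pa)
    return results


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), C])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(x, y, covariates=None,
                        names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Partial Pearson correlation of x and y given covariates.

    Computed as the correlation of the residuals after regressing the
    covariates out of both variables; the test uses df = n - 2 - k.
    With no covariates this reduces exactly to the plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    k = C.shape[1]
    n = len(x)
    if n <= k + 3:
        raise ValueError("need n > number of covariates + 3")
    if k and np.linalg.matrix_rank(np.column_stack([np.ones(n), C])) < k + 1:
        raise ValueError("collinear covariates")
    rx = _residualize(x, C)
    ry = _residualize(y, C)
    note = ""
    if np.allclose(ry, 0) or np.allclose(rx, 0):
        # y (or x) is an exact linear function of the covariates
        return CorrelationResult(names[0], names[1], 0.0, 1.0, n,
                                 method="partial",
                                 covariates=[f"c{i}" for i in range(k)],
                                 note="degenerate: residual is zero")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(names[0], names[1], r, p, n, method="partial",
                             covariates=[f"c{i}" for i in range(k)], note=note)


def standardized_regression(outcome, predictors,
                            outcome_name: str = "y",
                            predictor_names: list | None = None) -> RegressionResult:
    """OLS on z-scored outcome and predictors (betas on the correlation
    scale), with residual normality and homoscedasticity diagnostics.

    Homoscedasticity uses Levene's test on absolute residuals split at
    the fitted-value median. Rank-deficient designs raise, naming the
    aliased predictors.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("need n > number of predictors + 2")
    names = predictor_names or [f"x{j}" for j in range(p)]
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).any() or y.std(ddof=1) == 0:
        bad = [names[j] for j in np.where(sds == 0)[0]] or [outcome_name]
        raise ValueError(f"constant variable(s): {bad}")
    Xz = (X - X.mean(axis=0)) / sds
    rank = np.linalg.matrix_rank(Xz)
    if rank < p:
        _, R = np.linalg.qr(Xz)
        aliased = [names[j] for j in range(p) if abs(R[min(j, R.shape[0]-1), j]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased predictors: {aliased or names}")
    yz = (y - y.mean()) / y.std(ddof=1)
    model = sm.OLS(yz, sm.add_constant(Xz)).fit()
    resid = model.resid
    fitted = model.fittedvalues
    split = fitted <= np.median(fitted)
    lev = sps.levene(resid[split], resid[~split])
    # Shapiro-Wilk p-values are unreliable above n=5000; subsample
    sub = resid if len(resid) <= 5000 else np.asarray(resid)[
        np.linspace(0, len(resid) - 1, 5000).astype(int)]
    shap = sps.shapiro(sub)
    return RegressionResult(
        outcome=outcome_name, predictors=names,
        standardized_betas={nm: float(b) for nm, b in zip(names, model.params[1:])},
        p_values={nm: float(pv) for nm, pv in zip(names, model.pvalues[1:])},
        r_squared=float(model.rsquared),
        residual_shapiro_p=float(shap.pvalue),
        residual_levene_p=float(lev.pvalue),
    )


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy one-row-per-correlation frame for CSV export."""
    return pd.DataFrame([r.to_dict() for r in results])
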