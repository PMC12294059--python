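"""Nested-CV LASSO and bootstrap stability selection.

The regularization strength is chosen by inner cross-validation (MSE
loss) inside each outer fold, with imputation and z-scoring refit on
every training set so held-out rows never inform preprocessing. A
predictor is declared *robust* when its coefficient is nonzero in at
least 80% of bootstrap resamples and its mean absolute standardized
coefficient exceeds 0.25 — the stability-selection rule the pipeline is
built around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold, StratifiedKFold

from .preprocess import FeatureMatrix, knn_impute, zscore_fit_apply

DEFAULT_FREQ_THRESHOLD = 0.80
DEFAULT_BETA_THRESHOLD = 0.25


@dataclass
class FoldFit:
    fold: int
    lambda_: float
    coefficients: np.ndarray
    test_mse: float


@dataclass
class StabilityResult:
    predictors: list
    selection_frequency: np.ndarray
    mean_abs_beta: np.ndarray
    mean_abs_beta_nonzero: np.ndarray
    robust: np.ndarray
    n_bootstrap: int
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD
    beta_threshold: float = DEFAULT_BETA_THRESHOLD
    lambda_per_fold: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "predictor": self.predictors,
            "selection_frequency": self.selection_frequency,
            "mean_abs_beta": self.mean_abs_beta,
            "mean_abs_beta_nonzero": self.mean_abs_beta_nonzero,
            "robust": self.robust,
        })


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, FeatureMatrix):
        return X.X, list(X.feature_names)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100) -> np.ndarray:
    # data-driven maximum: smallest lambda shrinking every coefficient to 0
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / len(y)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 1e-4, n_lambda)


def _preprocess_fold(X_train, X_test, k_impute=5):
    names = [f"x{j}" for j in range(X_train.shape[1])]
    tr = FeatureMatrix(list(range(len(X_train))), names, X_train)
    te = FeatureMatrix(list(range(len(X_test))), names, X_test)
    if np.isnan(X_train).any() or np.isnan(X_test).any():
        k = min(k_impute, len(X_train))
        te = knn_impute(tr, te, k=k)
        tr = knn_impute(tr, None, k=k)
    te_z = zscore_fit_apply(tr, te)
    tr_z = zscore_fit_apply(tr)
    return tr_z.X, te_z.X


def _inner_select_lambda(X, y, n_inner: int, seed: int) -> tuple[float, np.ndarray]:
    grid = _lambda_grid(X, y)
    n_splits = min(n_inner, len(y))
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    model = LassoCV(alphas=grid, cv=cv, max_iter=50_000)
    yz = (y - y.mean()) / y.std(ddof=1)
    model.fit(X, yz)
    return float(model.alpha_), model.coef_.copy()


def lasso_path_cv(X, y, n_outer: int = 10, n_inner: int = 10,
                  seed: int = 0) -> list[FoldFit]:
    """Nested cross-validated LASSO.

    For each outer fold the inner CV picks the MSE-minimizing lambda
    from a 100-point log grid; the model refit on the outer training
    set at that lambda is scored on the held-out fold. Preprocessing
    (imputation, z-scoring) is refit inside every outer training set.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if np.nanstd(y) == 0:
        raise ValueError("constant outcome")
    if len(y) <= 2 * n_outer:
        raise ValueError("need n > 2 * n_outer")
    outer = KFold(n_splits=n_outer, shuffle=True, random_state=seed)
    fits: list[FoldFit] = []
    for fold, (tr_idx, te_idx) in enumerate(outer.split(Xm)):
        Xtr, Xte = _preprocess_fold(Xm[tr_idx], Xm[te_idx])
        ytr, yte = y[tr_idx], y[te_idx]
        lam, _ = _inner_select_lambda(Xtr, ytr, n_inner, seed + fold)
        mu, sd = ytr.mean(), ytr.std(ddof=1)
        model = Lasso(alpha=lam, max_iter=50_000)
        model.fit(Xtr, (ytr - mu) / sd)
        pred = model.predict(Xte) * sd + mu
        fits.append(FoldFit(fold, lam, model.coef_.copy(),
                            float(np.mean((pred - yte) ** 2))))
    return fits


def bootstrap_stability(X, y, groups=None, n_boot: int = 100,
                        n_inner: int = 10,
                        freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
                        beta_threshold: float = DEFAULT_BETA_THRESHOLD,
                        seed: int = 0) -> StabilityResult:
    """Bootstrap stability selection for LASSO predictors.

    Each of ``n_boot`` iterations resamples participants with
    replacement (stratified by ``groups`` when given), re-runs the
    inner-CV lambda selection on z-scored predictors, and records the
    nonzero pattern and standardized coefficients. ``mean_abs_beta``
    averages |beta| over all bootstraps (zeros included); the nonzero-
    only average is also reported. Robust requires selection frequency
    >= ``freq_threshold`` and all-bootstrap mean |beta| >
    ``beta_threshold``.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if np.nanstd(y) == 0:
        raise ValueError("constant outcome")
    rng = np.random.default_rng(seed)
    n, p = Xm.shape
    groups = None if groups is None else np.asarray(groups)
    sel = np.zeros(p)
    abs_beta = np.zeros(p)
    nonzero_beta_sum = np.zeros(p)
    lambdas = []
    for b in range(n_boot):
        for attempt in range(10):
            if groups is None:
                idx = rng.integers(0, n, size=n)
            else:
                idx = np.concatenate([
                    rng.choice(np.where(groups == g)[0],
                               size=(groups == g).sum(), replace=True)
                    for g in np.unique(groups)
                ])
            if np.std(y[idx]) > 0 and np.all(np.nanstd(Xm[idx], axis=0) > 0):
                break
        else:
            raise ValueError("could not draw a non-degenerate bootstrap sample")
        Xb, _ = _preprocess_fold(Xm[idx], Xm[idx][:1])
        lam, coef = _inner_select_lambda(Xb, y[idx], n_inner,
                                         int(rng.integers(0, 2**31 - 1)))
        lambdas.append(lam)
        nz = coef != 0
        sel += nz
        abs_beta += np.abs(coef)
        nonzero_beta_sum += np.where(nz, np.abs(coef), 0.0)
    freq = sel / n_boot
    mean_abs = abs_beta / n_boot
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_abs_nz = np.where(sel > 0, nonzero_beta_sum / np.maximum(sel, 1),
                               0.0)
    robust = (freq >= freq_threshold) & (mean_abs > beta_threshold)
    return StabilityResult(
        predictors=names, selection_frequency=freq, mean_abs_beta=mean_abs,
        mean_abs_beta_nonzero=mean_abs_nz, robust=robust, n_bootstrap=n_boot,
        freq_threshold=freq_threshold, beta_threshold=beta_threshold,
        lambda_per_fold=lambdas,
    )
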