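"""One-vs-rest discriminative validation of subtypes.

Each subtype is scored against the rest by a leave-one-out
cross-validated classifier: every participant receives a membership
score from a model trained on all other participants (preprocessing
refit within each training set). The AUC is the Mann-Whitney
probability that a random member outscores a random non-member, with
ties counted one half — a rank-based criterion that needs no class
weighting despite the small subtype sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .preprocess import FeatureMatrix
from .subtyping import SubtypeAssignment


@dataclass
class RocResult:
    subtype: str
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_positive: int
    n_negative: int
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")


def _labels(assignments) -> list[str]:
    return [a.subtype if isinstance(a, SubtypeAssignment) else a
            for a in assignments]


def loocv_scores(X: FeatureMatrix | np.ndarray, labels, target: str,
                 scorer: str = "logistic", C: float = 1.0,
                 seed: int = 0) -> np.ndarray:
    """Leave-one-out one-vs-rest membership scores for one subtype.

    ``logistic``: L2-regularized logistic regression probability,
    z-scoring refit on each training set. ``centroid``: negative
    Euclidean distance to the training-set target centroid (model-free
    alternative). The held-out participant never informs its own model.
    """
    Xm = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.array([lab == target for lab in _labels(labels)], dtype=int)
    n = len(y)
    if y.sum() < 2:
        raise ValueError(f"target {target!r} has fewer than 2 members")
    if n < 10:
        raise ValueError("need at least 10 participants")
    scores = np.zeros(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = Xm[mask], y[mask]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr_z = (Xtr - mu) / sd
        xi = (Xm[i] - mu) / sd
        if ytr.sum() == 0:
            scores[i] = -np.inf if scorer == "logistic" else -np.inf
            continue
        if scorer == "logistic":
            clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
            clf.fit(Xtr_z, ytr)
            scores[i] = clf.predict_proba(xi[None, :])[0, 1]
        elif scorer == "centroid":
            centroid = Xtr_z[ytr == 1].mean(axis=0)
            scores[i] = -float(np.linalg.norm(xi - centroid))
        else:
            raise ValueError(f"unknown scorer {scorer!r}")
    return scores


def roc_auc(scores, truth, subtype: str = "") -> RocResult:
    """ROC curve and U-statistic AUC.

    AUC is computed from midranks: the probability that a random
    positive outscores a random negative, ties counted one half. The
    ROC is a threshold sweep over the observed scores, starting at
    (0, 0) and ending at (1, 1), non-decreasing in both coordinates.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # midranks handle ties
    auc = (ranks[t].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    thresholds = np.unique(s)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        pred = s >= thr
        tpr.append(float((pred & t).sum() / n_pos))
        fpr.append(float((pred & ~t).sum() / n_neg))
    return RocResult(subtype=subtype, auc=float(auc),
                     fpr=np.array(fpr), tpr=np.array(tpr),
                     n_positive=n_pos, n_negative=n_neg,
                     thresholds=thresholds)


def validate_subtypes(X: FeatureMatrix | np.ndarray, assignments,
                      scorer: str = "logistic", min_members: int = 2,
                      seed: int = 0) -> dict[str, RocResult]:
    """One-vs-rest LOOCV ROC for every subtype with enough members."""
    labels = _labels(assignments)
    out: dict[str, RocResult] = {}
    for subtype in dict.fromkeys(labels):
        y = np.array([lab == subtype for lab in labels])
        if y.sum() < min_members:
            continue
        scores = loocv_scores(X, labels, subtype, scorer=scorer, seed=seed)
        out[subtype] = roc_auc(scores, y, subtype=subtype)
    return out


def plot_roc(results: dict[str, RocResult], path=None):
    """One-vs-rest ROC curves with the chance diagonal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for subtype, res in results.items():
        ax.plot(res.fpr, res.tpr, label=f"{subtype} (AUC={res.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="chance")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("One-vs-rest LOOCV ROC by subtype")
    ax.legend(fontsize=8, loc="lower right")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
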