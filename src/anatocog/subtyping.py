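"""Theory-seeded constrained clustering into anatomo-cognitive subtypes.

The eight-subtype taxonomy (cognitively intact, left/right
frontosubcortical, left/right posterior, left/right hippocampal, global)
is encoded as a correspondence matrix: one row per subtype, one column
per clustering feature (five cognitive-domain z-scores plus twelve
atrophy ratings), entries in {-1, 0, +1} giving the expected direction
of each subtype's signature. Scaling the matrix by a magnitude delta
yields theoretical centroids that seed standard Lloyd k-means; labels
inherit the seeding row's subtype name, so the refined clusters keep
their anatomical interpretation. Participants far from their assigned
centroid in Mahalanobis distance are flagged atypical but retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .cohort import (
    ATROPHY_COLUMNS,
    COGNITIVE_DOMAINS,
    CohortTable,
    HEMISPHERES,
    SUBTYPES,
)
from .preprocess import FeatureMatrix, knn_impute

#: Clustering feature space: cognitive domains then atrophy ratings.
CLUSTER_FEATURES: tuple[str, ...] = COGNITIVE_DOMAINS + ATROPHY_COLUMNS


class CorrespondenceMatrix:
    """Subtype-by-feature expected-signature matrix.

    Entries are -1 (expected deficit), 0 (spared) or +1 (expected
    atrophy); rows follow the canonical subtype order. Invariants: the
    intact row is all-zero, the global row is nonzero in every atrophy
    column, and left/right subtype pairs are hemisphere mirror images.
    """

    def __init__(self, frame: pd.DataFrame):
        if list(frame.index) != list(SUBTYPES):
            raise ValueError("rows must be the eight subtypes in canonical order")
        if list(frame.columns) != list(CLUSTER_FEATURES):
            raise ValueError("columns must be the clustering features in order")
        self.frame = frame.astype(float)
        self.validate()

    def validate(self) -> None:
        f = self.frame
        if not np.isin(f.to_numpy(), (-1.0, 0.0, 1.0)).all():
            raise ValueError("entries must be in {-1, 0, +1}")
        if (f.loc["cognitively_intact"] != 0).any():
            raise ValueError("intact row must be all-zero")
        if (f.loc["global", list(ATROPHY_COLUMNS)] == 0).any():
            raise ValueError("global row must be nonzero in every atrophy column")
        mirrored = [c.replace("_left", "_TMP").replace("_right", "_left")
                     .replace("_TMP", "_right") for c in CLUSTER_FEATURES]
        for left_s in ("left_frontosubcortical", "left_posterior",
                       "left_hippocampal"):
            right_s = left_s.replace("left_", "right_")
            lrow = f.loc[left_s, mirrored].to_numpy()
            if not np.array_equal(lrow, f.loc[right_s].to_numpy()):
                raise ValueError(f"{left_s}/{right_s} are not mirror images")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="subtype")

    @classmethod
    def from_csv(cls, path) -> "CorrespondenceMatrix":
        return cls(pd.read_csv(path, index_col="subtype"))

    @classmethod
    def default(cls) -> "CorrespondenceMatrix":
        """The canonical taxonomy: frontosubcortical = executive deficit
        + ipsilateral frontal atrophy (GCA-F, orbitofrontal, anterior
        cingulate, frontoinsular); posterior = visuospatial deficit +
        ipsilateral posterior atrophy; hippocampal = memory deficit +
        ipsilateral medial temporal atrophy; global = diffuse deficits
        and multiregional atrophy."""
        m = pd.DataFrame(0.0, index=list(SUBTYPES), columns=list(CLUSTER_FEATURES))
        for hemi in HEMISPHERES:
            fs = f"{hemi}_frontosubcortical"
            m.loc[fs, "executive"] = -1
            for region in ("gcaf", "orbitofrontal", "anterior_cingulate",
                           "frontoinsular"):
                m.loc[fs, f"{region}_{hemi}"] = 1
            m.loc[f"{hemi}_posterior", "visuospatial"] = -1
            m.loc[f"{hemi}_posterior", f"pa_{hemi}"] = 1
            m.loc[f"{hemi}_hippocampal", "memory"] = -1
            m.loc[f"{hemi}_hippocampal", f"mta_{hemi}"] = 1
        m.loc["global", list(COGNITIVE_DOMAINS)] = -1
        m.loc["global", list(ATROPHY_COLUMNS)] = 1
        return cls(m)


@dataclass
class SubtypeAssignment:
    participant_id: str
    subtype: str
    distance: float = np.nan
    atypical: bool = False


@dataclass
class ClusterValidation:
    mean_silhouette: float
    dunn_index: float
    sizes: dict
    percentages: dict
    ari_mean: float | None = None
    ari_iterations: int = 0


def theoretical_centroids(cm: CorrespondenceMatrix, delta: float = 1.0) -> np.ndarray:
    """Seed centroids: signature directions scaled by delta (z/SD units).

    Cognitive deficits point to -delta, atrophy to +delta; the intact
    centroid sits at the feature-space origin.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    return cm.values * delta


def build_clustering_features(table: CohortTable, k_impute: int = 5) -> FeatureMatrix:
    """Standardized clustering features for the PD participants.

    Cognitive domain scores and atrophy ratings are centred at the
    control-group mean (the healthy anchor, so the intact centroid at
    the origin is meaningful) and scaled to unit variance across the PD
    sample for distance comparability. Missing cognitive cells are
    kNN-imputed over the PD rows first. Controls are excluded: the
    taxonomy describes patient heterogeneity.
    """
    pd_rows = table.pd_rows()
    ctl = table.control_rows()
    cols = list(CLUSTER_FEATURES)
    X = pd_rows[cols].to_numpy(dtype=float)
    fm = FeatureMatrix(list(pd_rows["participant_id"]), cols, X)
    if np.isnan(X).any():
        fm = knn_impute(fm, None, k=min(k_impute, len(X)))
    anchor_rows = ctl if len(ctl) >= 2 else pd_rows
    center = anchor_rows[cols].mean(numeric_only=True).to_numpy(dtype=float)
    center = np.where(np.isnan(center), np.nanmean(fm.X, axis=0), center)
    scale = np.nanstd(fm.X, axis=0, ddof=1)
    scale[scale == 0] = 1.0
    out = fm.copy()
    out.X = (fm.X - center) / scale
    out.provenance = {c: "z-scored" for c in cols}
    return out


def constrained_kmeans(X: FeatureMatrix | np.ndarray, seeds: np.ndarray,
                       max_iter: int = 300, tol: float = 1e-6,
                       ids=None) -> tuple[list[SubtypeAssignment], np.ndarray, list[float]]:
    """Lloyd k-means initialized at theoretical centroids.

    Labels inherit the seeding row's subtype name. Ties in nearest-
    centroid assignment break toward the lowest subtype index. An
    emptied cluster is re-seeded at the point farthest from its current
    centroid. Returns (assignments, final centroids, per-iteration
    within-cluster sum of squares — non-increasing by construction).
    """
    if isinstance(X, FeatureMatrix):
        ids = list(X.ids)
        Xm = X.X
    else:
        Xm = np.asarray(X, dtype=float)
        ids = list(ids) if ids is not None else [str(i) for i in range(len(Xm))]
    k = seeds.shape[0]
    if len(Xm) < k:
        raise ValueError(f"need at least {k} participants")
    C = seeds.astype(float).copy()
    objective: list[float] = []
    labels = None
    for _ in range(max_iter):
        d2 = ((Xm[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        objective.append(float(d2[np.arange(len(Xm)), labels].sum()))
        newC = C.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                newC[j] = Xm[members].mean(axis=0)
            else:
                # re-seed an emptied cluster at the farthest point
                far = d2[np.arange(len(Xm)), labels].argmax()
                newC[j] = Xm[far]
        shift = float(np.abs(newC - C).max())
        C = newC
        if shift < tol:
            break
    d2 = ((Xm[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    objective.append(float(d2[np.arange(len(Xm)), labels].sum()))
    names = list(SUBTYPES) if k == len(SUBTYPES) else [f"cluster_{j}" for j in range(k)]
    assignments = [SubtypeAssignment(pid, names[lab])
                   for pid, lab in zip(ids, labels)]
    return assignments, C, objective


def _pooled_within_covariance(Xm: np.ndarray, labels: np.ndarray,
                              centroids: np.ndarray,
                              shrinkage: float) -> np.ndarray:
    n, p = Xm.shape
    resid = Xm - centroids[labels]
    k_used = len(np.unique(labels))
    df = max(n - k_used, 1)
    S = resid.T @ resid / df
    diag = np.diag(np.clip(np.diag(S), 1e-8, None))
    return (1 - shrinkage) * S + shrinkage * diag


def mahalanobis_atypicality(assignments: list[SubtypeAssignment],
                            X: FeatureMatrix | np.ndarray,
                            centroids: np.ndarray,
                            policy: str = "mean_plus_1sd",
                            shrinkage: float = 0.1) -> list[SubtypeAssignment]:
    """Mahalanobis distance to the assigned centroid plus atypicality flag.

    The covariance is the pooled within-cluster matrix shrunk toward its
    diagonal (small clusters make the raw pooled estimate unstable).
    Policies: ``md_gt_1`` flags distance > 1; ``mean_plus_1sd`` flags
    distance above the cohort mean + 1 SD of the distance distribution.
    Flagged participants keep their subtype label.
    """
    Xm = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if policy not in ("md_gt_1", "mean_plus_1sd"):
        raise ValueError(f"unknown policy {policy!r}")
    names = list(SUBTYPES) if centroids.shape[0] == len(SUBTYPES) else [
        f"cluster_{j}" for j in range(centroids.shape[0])]
    labels = np.array([names.index(a.subtype) for a in assignments])
    lam = shrinkage
    for _ in range(6):
        S = _pooled_within_covariance(Xm, labels, centroids, lam)
        try:
            L = np.linalg.cholesky(S)
            break
        except np.linalg.LinAlgError:
            lam = min(1.0, lam + 0.15)
    else:
        raise ValueError("pooled covariance singular even after shrinkage")
    diff = Xm - centroids[labels]
    sol = np.linalg.solve(L, diff.T)
    dist = np.sqrt((sol**2).sum(axis=0))
    if policy == "md_gt_1":
        cut = 1.0
    else:
        cut = dist.mean() + dist.std(ddof=1)
    out = []
    for a, d in zip(assignments, dist):
        out.append(SubtypeAssignment(a.participant_id, a.subtype,
                                     float(d), bool(d > cut)))
    return out


def stability_ari(X: FeatureMatrix | np.ndarray, reference_labels,
                  k: int = len(SUBTYPES), n_iter: int = 100,
                  seed: int = 0) -> tuple[list[float], float]:
    """Agreement of k-means++ restarts with the constrained partition.

    Runs ``n_iter`` single-start k-means++ clusterings and computes the
    adjusted Rand index of each against the reference partition; ARI is
    label-permutation invariant, so only the partitions matter.
    """
    Xm = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    ref = pd.Categorical(reference_labels).codes
    rng = np.random.default_rng(seed)
    aris = []
    for _ in range(n_iter):
        km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        aris.append(float(adjusted_rand_score(ref, km.fit_predict(Xm))))
    return aris, float(np.mean(aris))


def dunn_index(Xm: np.ndarray, labels: np.ndarray) -> float:
    """Minimum between-cluster point separation over maximum
    within-cluster diameter (single-linkage / complete-diameter Dunn)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    D = np.sqrt(((Xm[:, None, :] - Xm[None, :, :]) ** 2).sum(axis=2))
    max_diam = 0.0
    for c in uniq:
        idx = np.where(labels == c)[0]
        if len(idx) > 1:
            max_diam = max(max_diam, float(D[np.ix_(idx, idx)].max()))
    min_sep = np.inf
    for i, ci in enumerate(uniq):
        for cj in uniq[i + 1:]:
            a = np.where(labels == ci)[0]
            b = np.where(labels == cj)[0]
            min_sep = min(min_sep, float(D[np.ix_(a, b)].min()))
    if max_diam == 0.0:
        return np.inf
    return min_sep / max_diam


def internal_validity(X: FeatureMatrix | np.ndarray, assignments,
                      ari: tuple[list[float], float] | None = None) -> ClusterValidation:
    """Silhouette, Dunn index and the subtype size table.

    Mean silhouette uses Euclidean distance; by convention it is 0 when
    every point is identical (no structure either way). A clustering of
    only singletons has no defined silhouette and is reported as NaN.
    """
    Xm = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    labels = [a.subtype if isinstance(a, SubtypeAssignment) else a
              for a in assignments]
    codes = pd.Categorical(labels).codes
    counts = pd.Series(labels).value_counts()
    if (counts == 1).all():
        sil = float("nan")
    elif np.allclose(Xm, Xm[0]):
        sil = 0.0
    else:
        sil = float(silhouette_score(Xm, codes, metric="euclidean"))
    dunn = dunn_index(Xm, codes) if len(set(codes)) > 1 else float("nan")
    dist = subtype_distribution(labels)
    aris, ari_mean = (ari if ari is not None else ([], None))
    return ClusterValidation(
        mean_silhouette=sil, dunn_index=dunn,
        sizes=dict(dist["n"]), percentages=dict(dist["percent"]),
        ari_mean=ari_mean, ari_iterations=len(aris),
    )


def subtype_distribution(labels) -> pd.DataFrame:
    """Counts and 1-decimal percentages per subtype (canonical order
    first, then any other labels)."""
    labels = [a.subtype if isinstance(a, SubtypeAssignment) else a
              for a in labels]
    if not labels:
        raise ValueError("empty assignment list")
    counts = pd.Series(labels).value_counts()
    order = [s for s in SUBTYPES if s in counts.index] + [
        s for s in counts.index if s not in SUBTYPES]
    counts = counts.reindex(order).fillna(0).astype(int)
    total = counts.sum()
    pct = (100.0 * counts / total).round(1)
    return pd.DataFrame({"n": counts, "percent": pct})


def run_subtyping(table: CohortTable, cm: CorrespondenceMatrix | None = None,
                  delta: float = 1.0, policy: str = "mean_plus_1sd",
                  n_stability: int = 100, seed: int = 0) -> dict:
    """End-to-end subtyping of a cohort's PD participants.

    Builds the standardized clustering features, seeds Lloyd k-means at
    the theoretical centroids, flags Mahalanobis-atypical participants,
    and computes internal validity (silhouette, Dunn) plus k-means++
    stability (mean ARI over ``n_stability`` restarts).
    """
    cm = cm or CorrespondenceMatrix.default()
    feats = build_clustering_features(table)
    seeds = theoretical_centroids(cm, delta)
    assignments, centroids, objective = constrained_kmeans(feats, seeds)
    assignments = mahalanobis_atypicality(assignments, feats, centroids,
                                          policy=policy)
    labels = [a.subtype for a in assignments]
    if n_stability > 0:
        aris, ari_mean = stability_ari(feats, labels, n_iter=n_stability,
                                       seed=seed)
    else:
        aris, ari_mean = [], None
    validation = internal_validity(feats, assignments, ari=(aris, ari_mean))
    return {
        "features": feats,
        "assignments": assignments,
        "centroids": centroids,
        "objective": objective,
        "validation": validation,
        "distribution": subtype_distribution(labels),
    }


def assignments_to_frame(assignments: list[SubtypeAssignment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": a.participant_id, "subtype": a.subtype,
        "mahalanobis_distance": a.distance, "atypical": a.atypical,
    } for a in assignments])
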