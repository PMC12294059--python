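"""Cohort validation and leakage-free preprocessing.

Preprocessing mirrors how the analysis handles mixed-type cohort data:
categorical variables are one-hot encoded, missing values are imputed by
k-nearest neighbours (k=5) fitted on training rows only, and continuous
scores are z-scored with training-fold statistics — imputation and
scaling are always refit inside each cross-validation training set so no
information leaks from held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer
from sklearn.model_selection import StratifiedKFold

from .cohort import (
    ATROPHY_COLUMNS,
    COGNITIVE_DOMAINS,
    CohortTable,
    EDUCATION_LEVELS,
    GROUP_LEVELS,
    HANDEDNESS_LEVELS,
    SCREEN_TESTS,
    SEX_LEVELS,
    atrophy_scale_max,
)


@dataclass
class FeatureMatrix:
    """Numeric participants-by-features matrix with provenance.

    ``provenance`` maps each feature name to one of ``raw``,
    ``one-hot(level)`` or ``z-scored``.
    """

    ids: list
    feature_names: list
    X: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match ids/features")

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            list(self.ids), list(self.feature_names), self.X.copy(),
            dict(self.provenance),
        )

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.feature_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.ids, columns=self.feature_names)


@dataclass
class FoldPlan:
    """Partition of participants into cross-validation folds."""

    n_folds: int
    assignments: dict
    stratify_key: str = "group"

    def fold_ids(self, fold: int) -> list:
        return [p for p, f in self.assignments.items() if f == fold]

    def validate(self) -> None:
        folds = np.array(list(self.assignments.values()))
        sizes = np.bincount(folds, minlength=self.n_folds)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes differ by more than 1")


def validate_cohort(table: CohortTable) -> list[str]:
    """Check ranges, factor levels and id uniqueness.

    Returns a list of human-readable violations (empty when the table is
    well formed); never mutates or raises on bad data.
    """
    df = table.data
    out: list[str] = []
    dup = df["participant_id"][df["participant_id"].duplicated()]
    for pid in dup.unique():
        out.append(f"duplicated participant_id {pid!r}")
    checks = [
        ("group", GROUP_LEVELS),
        ("sex", SEX_LEVELS),
        ("handedness", HANDEDNESS_LEVELS),
        ("education", EDUCATION_LEVELS),
    ]
    for col, levels in checks:
        bad = df.loc[df[col].notna() & ~df[col].isin(levels)]
        for idx, val in bad[col].items():
            out.append(f"row {idx}: {col}={val!r} not in {levels}")
    for col in ATROPHY_COLUMNS:
        hi = atrophy_scale_max(col)
        vals = df[col]
        bad = df.loc[vals.notna() & ((vals < 0) | (vals > hi) | (vals % 1 != 0))]
        for idx, val in bad[col].items():
            out.append(f"row {idx}: {col}={val} outside integer range [0, {hi}]")
    if (df["age"] < 0).any():
        for idx in df.index[df["age"] < 0]:
            out.append(f"row {idx}: negative age")
    return out


def make_folds(table: CohortTable, n_folds: int = 10, seed: int = 0,
               stratify_by: str = "group") -> FoldPlan:
    """Stratified fold partition, reproducible given the seed."""
    df = table.data
    strata = df[stratify_by].astype(str).to_numpy()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments: dict = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(df)), strata)):
        for i in test_idx:
            assignments[df["participant_id"].iloc[i]] = fold
    return FoldPlan(n_folds=n_folds, assignments=assignments,
                    stratify_key=stratify_by)


def one_hot_education(table: CohortTable) -> pd.DataFrame:
    """One-hot encoding of the 6-level education factor.

    The block is mutually exclusive and exhaustive: each participant's
    row sums to exactly 1.
    """
    cat = pd.Categorical(table.data["education"], categories=EDUCATION_LEVELS)
    dummies = pd.get_dummies(cat, prefix="education").astype(float)
    dummies.index = table.data["participant_id"]
    return dummies


def education_ordinal(table: CohortTable) -> pd.Series:
    """Education as an ordered integer (0 = primary ... 5 = doctorate)."""
    return pd.Series(
        pd.Categorical(table.data["education"], categories=EDUCATION_LEVELS,
                       ordered=True).codes,
        index=table.data["participant_id"], name="education_ordinal",
    )


def cognitive_feature_matrix(table: CohortTable,
                             include_screens: bool = False) -> FeatureMatrix:
    """Cognitive scores (and optionally the global screens) as a
    FeatureMatrix; missing cells stay NaN for downstream imputation."""
    cols = list(COGNITIVE_DOMAINS) + (list(SCREEN_TESTS) if include_screens else [])
    X = table.data[cols].to_numpy(dtype=float)
    return FeatureMatrix(
        ids=list(table.data["participant_id"]), feature_names=cols, X=X,
        provenance={c: "raw" for c in cols},
    )


def knn_impute(train: FeatureMatrix, apply_to: FeatureMatrix | None = None,
               k: int = 5) -> FeatureMatrix:
    """Impute missing cells from the k nearest training rows.

    Distances are NaN-aware Euclidean over the shared observed features;
    a missing cell is replaced by the mean of its k nearest donors'
    values. Training rows never see ``apply_to`` (leakage contract);
    passing ``apply_to=None`` imputes the training matrix itself.
    """
    if train.feature_names != (apply_to.feature_names
                               if apply_to is not None else train.feature_names):
        raise ValueError("train and apply_to feature names differ")
    n_train = train.X.shape[0]
    if k > n_train:
        raise ValueError(f"k={k} exceeds available train rows ({n_train})")
    all_missing = np.isnan(train.X).all(axis=0)
    if all_missing.any():
        bad = [train.feature_names[j] for j in np.where(all_missing)[0]]
        raise ValueError(f"all-missing feature(s) in train: {bad}")
    target = train if apply_to is None else apply_to
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    imputer.fit(train.X)
    filled = imputer.transform(target.X)
    out = target.copy()
    out.X = filled
    return out


def zscore_fit_apply(train: FeatureMatrix, apply_to: FeatureMatrix | None = None,
                     ddof: int = 1) -> FeatureMatrix:
    """Z-score ``apply_to`` with training-fold means and SDs.

    Applying a fold's transform to itself yields column means 0 and SDs
    1; a zero-variance training column is an error naming the column.
    """
    if apply_to is not None and train.feature_names != apply_to.feature_names:
        raise ValueError("train and apply_to feature names differ")
    mu = np.nanmean(train.X, axis=0)
    sd = np.nanstd(train.X, axis=0, ddof=ddof)
    zero = np.where(sd <= 0)[0]
    if len(zero):
        names = [train.feature_names[j] for j in zero]
        raise ValueError(f"zero-variance column(s): {names}")
    target = train if apply_to is None else apply_to
    out = target.copy()
    out.X = (target.X - mu) / sd
    out.provenance = {c: "z-scored" for c in out.feature_names}
    return out
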