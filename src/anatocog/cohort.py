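"""Cohort table schema and I/O.

A cohort is a flat participants-by-features table: demographics, group
label (PD vs. control), global cognitive screens, domain-level cognitive
z-scores, and 12 ordinal visual MRI atrophy ratings (six regions rated
per hemisphere). The canonical in-memory container is a pandas DataFrame
wrapped by :class:`CohortTable`, which carries the column dictionary and
a missingness mask (missing cells are NaN in the frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Subtype taxonomy, in the fixed canonical order used everywhere
#: (centroid rows, distribution tables, tie-breaking).
SUBTYPES: tuple[str, ...] = (
    "cognitively_intact",
    "left_frontosubcortical",
    "right_frontosubcortical",
    "left_posterior",
    "right_posterior",
    "left_hippocampal",
    "right_hippocampal",
    "global",
)

#: Cognitive domains entering the clustering feature space (z units).
COGNITIVE_DOMAINS: tuple[str, ...] = (
    "executive",
    "attention_wm",
    "visuospatial",
    "memory",
    "language_fluency",
)

#: Global cognitive screens (raw scale units, not clustered on).
SCREEN_TESTS: tuple[str, ...] = (
    "moca",
    "pdcrs_subcortical",
    "pdcrs_cortical",
    "pdcrs_total",
)

#: Visual rating regions and their maximum scale value.
#: MTA (Scheltens) is 0-4; Koedam PA, GCA-F and the three Harper frontal
#: scales (orbitofrontal, anterior cingulate, frontoinsular) are 0-3.
ATROPHY_SCALE_MAX: dict[str, int] = {
    "mta": 4,
    "pa": 3,
    "gcaf": 3,
    "orbitofrontal": 3,
    "anterior_cingulate": 3,
    "frontoinsular": 3,
}

HEMISPHERES: tuple[str, ...] = ("left", "right")

#: 12 atrophy rating columns, region-major, left before right.
ATROPHY_COLUMNS: tuple[str, ...] = tuple(
    f"{region}_{hemi}" for region in ATROPHY_SCALE_MAX for hemi in HEMISPHERES
)

EDUCATION_LEVELS: tuple[str, ...] = (
    "primary",
    "secondary",
    "highschool_vocational",
    "preuniversity",
    "university",
    "doctorate",
)

SEX_LEVELS: tuple[str, ...] = ("M", "F")
HANDEDNESS_LEVELS: tuple[str, ...] = ("right", "left", "ambidextrous")
GROUP_LEVELS: tuple[str, ...] = ("PD", "control")

#: Columns that may legitimately carry missing values (MCAR mask applies
#: to cognitive measurements only).
MASKABLE_COLUMNS: tuple[str, ...] = COGNITIVE_DOMAINS + SCREEN_TESTS


def atrophy_scale_max(column: str) -> int:
    """Scale maximum for an atrophy rating column such as ``mta_left``."""
    region = column.rsplit("_", 1)[0]
    return ATROPHY_SCALE_MAX[region]


@dataclass
class AtrophyProfile:
    """Twelve bounded ordinal ratings for one participant.

    Values are keyed by ``<region>_<hemisphere>`` and each must lie in
    ``[0, scale_max]`` for its scale.
    """

    ratings: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(ATROPHY_COLUMNS) - set(self.ratings)
        if missing:
            raise ValueError(f"missing atrophy ratings: {sorted(missing)}")
        for col, val in self.ratings.items():
            hi = atrophy_scale_max(col)
            if not (0 <= int(val) <= hi):
                raise ValueError(f"rating {col}={val} outside [0, {hi}]")


class CohortTable:
    """Participants-by-features cohort with missingness carried as NaN.

    Parameters
    ----------
    data
        One row per participant. Required columns: ``participant_id``,
        ``group``, demographics, the cognitive domain scores, the screen
        tests and the 12 atrophy columns. ``true_subtype`` is present
        only for synthetic cohorts (generator ground truth).
    """

    REQUIRED = (
        ["participant_id", "group", "age", "sex", "handedness", "education"]
        + list(COGNITIVE_DOMAINS)
        + list(SCREEN_TESTS)
        + list(ATROPHY_COLUMNS)
    )

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        self.data = data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask over the maskable (cognitive) cells."""
        return self.data[list(MASKABLE_COLUMNS)].isna()

    def pd_rows(self) -> pd.DataFrame:
        return self.data[self.data["group"] == "PD"]

    def control_rows(self) -> pd.DataFrame:
        return self.data[self.data["group"] == "control"]

    def atrophy_profile(self, participant_id: str) -> AtrophyProfile:
        row = self.data.set_index("participant_id").loc[participant_id]
        return AtrophyProfile(
            {c: int(row[c]) for c in ATROPHY_COLUMNS}
        )

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write one row per participant; missing cells as empty fields."""
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, dtype={"participant_id": str})
        for col in ATROPHY_COLUMNS:
            if col in df.columns:
                df[col] = df[col].astype(int)
        if "true_subtype" in df.columns:
            df["true_subtype"] = df["true_subtype"].where(
                df["true_subtype"].notna(), None
            )
        return cls(df)

    def equals(self, other: "CohortTable") -> bool:
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns):
            return False
        for col in a.columns:
            if a[col].dtype.kind == "f":
                ok = np.allclose(a[col], b[col], equal_nan=True, atol=1e-12)
            else:
                ok = a[col].fillna("∅").equals(b[col].fillna("∅"))
            if not ok:
                return False
        return True
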