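"""Synthetic cohort generator.

Emulates an early-Parkinson's cohort of 81 patients and 20 controls with
the statistical structure the subtyping pipeline assumes: each PD
participant carries a latent anatomo-cognitive subtype that shifts a set
of cognitive-domain z-scores downward and a set of latent regional
atrophy intensities upward; ordinal visual ratings arise by thresholding
the latent atrophy (a proportional-odds-style link), never by rounding
or clipping, so ratings are in range by construction.

The ``paper_like_config`` preset plants the eight-subtype taxonomy
(cognitively intact, left/right frontosubcortical, left/right posterior,
left/right hippocampal, global) at the reference cohort's subtype
proportions, with hemisphere-mirrored signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    ATROPHY_COLUMNS,
    ATROPHY_SCALE_MAX,
    COGNITIVE_DOMAINS,
    CohortTable,
    EDUCATION_LEVELS,
    HEMISPHERES,
    SUBTYPES,
)

#: Reference subtype counts out of 81 PD participants, canonical order.
REFERENCE_SUBTYPE_COUNTS: tuple[int, ...] = (33, 10, 9, 7, 6, 5, 4, 7)

#: Reference subtype proportions (sum to 1 exactly).
REFERENCE_PROPORTIONS: dict[str, float] = {
    s: c / 81 for s, c in zip(SUBTYPES, REFERENCE_SUBTYPE_COUNTS)
}

#: Latent thresholds per region: rating = number of cutpoints strictly
#: below the latent. Chosen so a zero-centred (healthy) latent with the
#: default noise concentrates at rating 0-1.
DEFAULT_CUTPOINTS: dict[str, tuple[float, ...]] = {
    region: (
        (0.5, 1.25, 2.0, 2.75) if hi == 4 else (0.5, 1.25, 2.0)
    )
    for region, hi in ATROPHY_SCALE_MAX.items()
}

# Demographic marginals of the reference cohort (age in years; sex,
# handedness and education as level frequencies).
_PD_AGE = (66.46, 10.86)
_CONTROL_AGE = (62.05, 11.02)
_PD_SEX_P_MALE = 45 / 81
_CONTROL_SEX_P_MALE = 8 / 20
_PD_HANDEDNESS = (78 / 81, 2 / 81, 1 / 81)
_CONTROL_HANDEDNESS = (18 / 20, 2 / 20, 0.0)
_PD_EDUCATION = (14, 34, 11, 8, 5, 9)
_CONTROL_EDUCATION = (7, 11, 1, 0, 1, 0)

# Global-screen anchors: (control mean, PD group shift, slope per mean
# domain z, residual sd, clip range).
_SCREEN_MODEL = {
    "moca": (27.15, -4.1, 3.4, 1.5, (0.0, 30.0)),
    "pdcrs_subcortical": (87.25, -26.0, 10.0, 5.0, (0.0, 134.0)),
    "pdcrs_cortical": (29.90, -2.2, 1.5, 0.8, (0.0, 30.0)),
}


def subtype_signature(delta: float = 1.0) -> tuple[dict, dict]:
    """Expected anatomo-cognitive signature of each subtype.

    Returns ``(domain_effects, atrophy_signature)``: nested maps
    subtype -> feature -> shift. Cognitive shifts are ≤ 0 (deficits, in
    z units); atrophy shifts are ≥ 0 (latent SD units). Left/right
    subtype pairs are exact hemisphere mirror images; the global
    subtype is impaired in every domain and atrophic in every region.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    dom: dict[str, dict[str, float]] = {s: {} for s in SUBTYPES}
    atr: dict[str, dict[str, float]] = {s: {} for s in SUBTYPES}
    for hemi in HEMISPHERES:
        fs = f"{hemi}_frontosubcortical"
        dom[fs]["executive"] = -delta
        for region in ("gcaf", "orbitofrontal", "anterior_cingulate", "frontoinsular"):
            atr[fs][f"{region}_{hemi}"] = delta
        post = f"{hemi}_posterior"
        dom[post]["visuospatial"] = -delta
        atr[post][f"pa_{hemi}"] = delta
        hipp = f"{hemi}_hippocampal"
        dom[hipp]["memory"] = -delta
        atr[hipp][f"mta_{hemi}"] = delta
    dom["global"] = {d: -delta for d in COGNITIVE_DOMAINS}
    atr["global"] = {c: delta for c in ATROPHY_COLUMNS}
    return dom, atr


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    ``domain_effects`` maps subtype -> cognitive domain -> standardized
    shift (z units, ≤ 0 for deficits); ``atrophy_signature`` maps
    subtype -> rating column -> latent shift (SD units, ≥ 0 for
    atrophy). ``noise_sd`` is the residual SD shared by the cognitive
    scores and the latent atrophy intensities. ``age_executive_beta``
    and ``education_fluency_beta`` couple demographics to cognition
    (older age lowers executive scores, more education raises fluency).
    """

    n_pd: int = 81
    n_control: int = 20
    subtype_proportions: dict = field(
        default_factory=lambda: dict(REFERENCE_PROPORTIONS)
    )
    domain_effects: dict = field(default_factory=lambda: subtype_signature(1.0)[0])
    atrophy_signature: dict = field(default_factory=lambda: subtype_signature(1.0)[1])
    noise_sd: float = 0.25
    missing_rate: float = 0.005
    seed: int = 0
    age_executive_beta: float = -0.10
    education_fluency_beta: float = 0.10
    cutpoints: dict = field(default_factory=lambda: {
        k: tuple(v) for k, v in DEFAULT_CUTPOINTS.items()
    })

    def validate(self) -> None:
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype_proportions sum to {total}, not 1")
        unknown = set(self.subtype_proportions) - set(SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtypes: {sorted(unknown)}")
        if any(p < 0 for p in self.subtype_proportions.values()):
            raise ValueError("subtype proportions must be nonnegative")
        if not (0.0 <= self.missing_rate <= 0.05):
            raise ValueError("missing_rate must be in [0, 0.05]")
        if self.n_pd < len(SUBTYPES):
            raise ValueError("n_pd must be at least the number of subtypes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for region, cuts in self.cutpoints.items():
            arr = np.asarray(cuts, dtype=float)
            if arr.ndim != 1 or len(arr) != ATROPHY_SCALE_MAX[region]:
                raise ValueError(f"cutpoints for {region} must have length "
                                 f"{ATROPHY_SCALE_MAX[region]}")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"cutpoints for {region} must be strictly increasing")

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        blob = asdict(self)
        blob["cutpoints"] = {k: list(v) for k, v in blob["cutpoints"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(blob, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            blob = yaml.safe_load(fh)
        blob["cutpoints"] = {k: tuple(v) for k, v in blob["cutpoints"].items()}
        return cls(**blob)


def paper_like_config(delta: float = 1.0, seed: int = 0, **overrides) -> GeneratorConfig:
    """The documented preset: reference proportions and mirrored
    subtype signatures scaled by ``delta`` (z/SD units).

    ``delta >= 1.5`` corresponds to strong subtype separation.
    """
    dom, atr = subtype_signature(delta)
    cfg = GeneratorConfig(
        domain_effects=dom, atrophy_signature=atr, seed=seed, **overrides
    )
    cfg.validate()
    return cfg


def ordinal_from_latent(latent, cutpoints) -> np.ndarray | int:
    """Map latent intensities to ordinal ratings.

    The rating is the number of cutpoints strictly below the latent
    value, so the result lies in ``[0, len(cutpoints)]`` with no
    clipping. Cutpoints must be strictly increasing.
    """
    cuts = np.asarray(cutpoints, dtype=float)
    if cuts.ndim != 1 or len(cuts) == 0:
        raise ValueError("cutpoints must be a non-empty 1-D sequence")
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    out = np.searchsorted(cuts, np.asarray(latent, dtype=float), side="left")
    if np.isscalar(latent) or np.ndim(latent) == 0:
        return int(out)
    return out


def _draw_education(rng, counts, n) -> np.ndarray:
    p = np.asarray(counts, dtype=float)
    return rng.choice(len(EDUCATION_LEVELS), size=n, p=p / p.sum())


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Generate a synthetic cohort. Deterministic given ``config.seed``.

    PD participants draw a true subtype from ``subtype_proportions``;
    cognitive domain scores are the subtype's domain shift plus a
    demographic term plus Gaussian noise; atrophy ratings arise by
    thresholding a latent Gaussian shifted by the subtype's atrophy
    signature. Missing cells are MCAR at ``missing_rate`` over the
    cognitive measurements only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pd, n_c = config.n_pd, config.n_control
    n = n_pd + n_c

    group = np.array(["PD"] * n_pd + ["control"] * n_c)
    probs = np.array([config.subtype_proportions.get(s, 0.0) for s in SUBTYPES])
    sub_idx = rng.choice(len(SUBTYPES), size=n_pd, p=probs)
    true_subtype = [SUBTYPES[i] for i in sub_idx] + [None] * n_c

    age = np.concatenate([
        rng.normal(*_PD_AGE, size=n_pd),
        rng.normal(*_CONTROL_AGE, size=n_c),
    ]).clip(35, 95).round(1)
    sex = np.concatenate([
        rng.choice(["M", "F"], size=n_pd, p=[_PD_SEX_P_MALE, 1 - _PD_SEX_P_MALE]),
        rng.choice(["M", "F"], size=n_c,
                   p=[_CONTROL_SEX_P_MALE, 1 - _CONTROL_SEX_P_MALE]),
    ])
    handed = np.concatenate([
        rng.choice(["right", "left", "ambidextrous"], size=n_pd, p=_PD_HANDEDNESS),
        rng.choice(["right", "left", "ambidextrous"], size=n_c, p=_CONTROL_HANDEDNESS),
    ])
    edu_idx = np.concatenate([
        _draw_education(rng, _PD_EDUCATION, n_pd),
        _draw_education(rng, _CONTROL_EDUCATION, n_c),
    ])
    education = np.array([EDUCATION_LEVELS[i] for i in edu_idx])

    # Cognitive domain z-scores: subtype shift + demographic coupling + noise.
    age_z = (age - _PD_AGE[0]) / _PD_AGE[1]
    edu_z = (edu_idx - edu_idx.mean()) / max(edu_idx.std(), 1e-9)
    cog = rng.normal(0.0, config.noise_sd, size=(n, len(COGNITIVE_DOMAINS)))
    for i in range(n_pd):
        eff = config.domain_effects.get(true_subtype[i], {})
        for j, d in enumerate(COGNITIVE_DOMAINS):
            cog[i, j] += eff.get(d, 0.0)
    j_exec = COGNITIVE_DOMAINS.index("executive")
    j_flu = COGNITIVE_DOMAINS.index("language_fluency")
    cog[:, j_exec] += config.age_executive_beta * age_z
    cog[:, j_flu] += config.education_fluency_beta * edu_z

    # Atrophy: latent Gaussian shifted by the signature, then thresholded.
    latent = rng.normal(0.0, config.noise_sd, size=(n, len(ATROPHY_COLUMNS)))
    for i in range(n_pd):
        sig = config.atrophy_signature.get(true_subtype[i], {})
        for j, col in enumerate(ATROPHY_COLUMNS):
            latent[i, j] += sig.get(col, 0.0)
    atrophy = np.zeros_like(latent, dtype=int)
    for j, col in enumerate(ATROPHY_COLUMNS):
        region = col.rsplit("_", 1)[0]
        atrophy[:, j] = ordinal_from_latent(latent[:, j], config.cutpoints[region])

    # Global screens anchored to the reference cohort's group means.
    mean_z = cog.mean(axis=1)
    is_pd = (group == "PD").astype(float)
    screens = {}
    for name, (c_mean, pd_shift, slope, sd, clip) in _SCREEN_MODEL.items():
        raw = c_mean + pd_shift * is_pd + slope * mean_z + rng.normal(0, sd, n)
        screens[name] = np.clip(raw, *clip).round(1)
    screens["pdcrs_total"] = (
        screens["pdcrs_subcortical"] + screens["pdcrs_cortical"]
    ).round(1)

    df = pd.DataFrame({
        "participant_id": [f"P{i + 1:03d}" for i in range(n)],
        "group": group,
        "true_subtype": true_subtype,
        "age": age,
        "sex": sex,
        "handedness": handed,
        "education": education,
    })
    for j, d in enumerate(COGNITIVE_DOMAINS):
        df[d] = np.round(cog[:, j], 4)
    for name in ("moca", "pdcrs_subcortical", "pdcrs_cortical", "pdcrs_total"):
        df[name] = screens[name]
    for j, col in enumerate(ATROPHY_COLUMNS):
        df[col] = atrophy[:, j]

    if config.missing_rate > 0:
        maskable = list(COGNITIVE_DOMAINS) + list(screens)
        mask = rng.random((n, len(maskable))) < config.missing_rate
        for j, col in enumerate(maskable):
            df.loc[mask[:, j], col] = np.nan

    return CohortTable(df)
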