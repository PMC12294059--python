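# Methods

## The subtyping model

Each PD participant is represented by 17 clustering features: five
cognitive-domain z-scores (executive, attention/working memory,
visuospatial, memory, language/fluency) and twelve ordinal visual
atrophy ratings (MTA, posterior atrophy, GCA-frontal, orbitofrontal,
anterior cingulate, frontoinsular; each per hemisphere). Features are
standardized before clustering: centred at the control-group mean (the
healthy anchor, so the intact subtype's centroid at the origin is
meaningful) and scaled to unit variance across the PD sample so
cognitive and atrophy coordinates are distance-comparable. When a
cohort has fewer than two controls the PD sample mean is the anchor
instead. Missing cognitive cells are kNN-imputed (k = 5) over the PD
rows before standardization.

The eight-subtype taxonomy is fixed a priori as a correspondence matrix
C (8 subtypes × 17 features, entries −1/0/+1): frontosubcortical =
executive deficit with ipsilateral GCA-F, orbitofrontal, anterior
cingulate and frontoinsular atrophy; posterior = visuospatial deficit
with ipsilateral posterior atrophy; hippocampal = memory deficit with
ipsilateral medial temporal atrophy; global = deficits in every domain
with multiregional atrophy; intact = all zero. Left/right rows are
exact hemisphere mirrors, and the matrix is user-editable as a CSV.

Clustering is Lloyd k-means initialized at the theoretical centroids
δ·C (δ defaults to 1.0 z/SD; δ ≥ 1.5 is the strong-separation regime
used in the validation runs). k is fixed at 8 — the taxonomy is a
design commitment, not a model-selection target. Ties in nearest-
centroid assignment break toward the lowest subtype index; an emptied
cluster is re-seeded at the point farthest from its centroid; the
within-cluster sum of squares is non-increasing across iterations and
convergence is declared when the maximum centroid shift falls below
1e-6 (cap 300 iterations).

## Atypicality

Mahalanobis distance to the assigned centroid uses the pooled
within-cluster covariance with shrinkage λ = 0.1 toward its diagonal:
the smallest subtypes have single-digit membership, so the unshrunk
pooled estimate is unstable; λ escalates automatically (up to 1.0,
i.e. fully diagonal) if the matrix is still not positive definite.
Two flagging policies are implemented because "1 SD Mahalanobis
distance" is ambiguous in a 17-dimensional space: `md_gt_1` (raw
distance > 1, which would flag most of any high-dimensional cohort) and
the default `mean_plus_1sd` (distance above the cohort mean + 1 SD of
the distance distribution, which flags the tail — of the order of 10%
of participants). Flagged participants keep their subtype label and
remain in all group-level outputs.

## Validation metrics

- **Stability**: 100 single-start k-means++ clusterings; the adjusted
  Rand index of each against the constrained partition, averaged. ARI
  is label-permutation invariant and ≈ 0 for independent partitions.
- **Internal validity**: mean Euclidean silhouette (0 by convention
  when all points coincide; undefined for singleton-only clusterings)
  and the Dunn index (minimum between-cluster point separation over
  maximum within-cluster diameter).
- **Discrimination**: per subtype with ≥ 2 members, one-vs-rest LOOCV
  scores from an L2-regularized logistic model (C = 1) refit with
  z-scoring inside every leave-one-out training set; a model-free
  negative-distance-to-centroid scorer is available as a cross-check.
  AUC is the midrank U-statistic (ties count ½). No class weighting is
  applied despite imbalance — AUC is rank-based — but note that LOOCV
  is pessimistically biased under the null: with no signal the held-out
  participant's class is always underrepresented in training, so null
  AUCs fall below 0.5 at small n (≈ 0.38 at n = 30, ≈ 0.44 at n = 100
  in our simulations). Reported AUCs for real structure are therefore
  conservative.

## Supporting statistics

Two-group comparisons are gated by per-group Shapiro-Wilk (α = 0.05):
Welch's t with Satterthwaite df in parametric cases, tie-corrected
two-sided Mann-Whitney U otherwise; a constant sample routes to the
rank test since normality is undefined for it. Chi-square applies the
Yates continuity correction exactly for 2×2 tables (the convention
under which published 2×2 statistics reproduce) and no correction for
larger tables. Cohen's d uses the pooled SD with the normal-theory
CI, SE(d) = √((n_a+n_b)/(n_a·n_b) + d²/(2(n_a+n_b))); Hedges'
correction is available but off by default. All of these accept
(n, mean, sd) summaries so printed tables can be checked without raw
data. The MANOVA over the 12 ratings reports Wilks' Λ (Pillai
optional) with Bonferroni- or BH-corrected univariate follow-ups; a
single-column input reduces exactly to one-way ANOVA. Two-sided
p-values are used throughout.

Correlation analyses use pairwise-complete deletion (so n varies per
pair, as in published correlation tables) with Bonferroni or
Benjamini-Hochberg adjustment across the computed pairs; partial
correlations regress the covariates out of both variables and test the
residual correlation at df = n − 2 − k. Education enters regressions
as an ordinal integer; one-hot encoding is provided for multivariate
models. Standardized regressions z-score outcome and predictors
(betas on the correlation scale) and always report Shapiro-Wilk
residual normality and a Levene test on absolute residuals split at the
fitted-value median. Negative-keyed tests (e.g. solution time: more =
worse) are not sign-flipped; raw orientation is preserved.

LASSO: λ is selected by inner 10-fold CV (MSE loss) on a 100-point
log-spaced grid whose maximum is the smallest λ nulling every
coefficient; nested outer folds give honest error, with imputation and
z-scoring refit inside every training set. Stability selection runs
100 bootstrap resamples (stratified by group when one is supplied,
preserving PD/control balance); a predictor is robust when its
coefficient is nonzero in ≥ 80% of resamples and its mean |β| — averaged
over *all* resamples, zeros included; the nonzero-only average is also
reported — exceeds 0.25. Degenerate resamples (constant outcome or
predictor) are redrawn up to 10 times.

## The synthetic cohort generator

Real patient-level data of this kind is not publicly deposited, so the
generator is the test bed: 81 PD + 20 controls by default. Each PD
participant draws a true subtype from the reference proportions
(40.7 / 12.3 / 11.1 / 8.6 / 7.4 / 6.2 / 4.9 / 8.6%). Cognitive domain
scores are subtype shift + demographic coupling + N(0, noise_sd);
atrophy ratings threshold a latent Gaussian (subtype shift +
N(0, noise_sd)) at fixed cutpoints — a proportional-odds-style link
that keeps ratings in range by construction, with healthy latents
concentrating at ratings 0–1 (cutpoints 0.5/1.25/2.0(/2.75 for the
0–4 MTA scale)). Demographics match the reference cohort's marginals
(PD age ~ N(66.46, 10.86²), 45/36 M/F, the published handedness and
education frequencies); age lowers executive scores and education
raises fluency with small default couplings (±0.10 per SD), matching
the reported signs. Global screens (MoCA, PD-CRS) are affine in the
participant's mean domain z with group-level anchors, clipped to their
scales. Missingness is MCAR over cognitive cells only (default rate
0.5%); the true mechanism in clinical data is unknown.

**Preset calibration.** The documented "paper-like" preset sets the
signature magnitudes to ±δ exactly on the correspondence-matrix
support and `noise_sd = 0.25`. The noise level was chosen by matching
the preset, at strong separation δ = 1.5, to the clustering-quality
regime reported for this design — mean silhouette around 0.5 and
k-means++ ARI around 0.9 on an 81-participant cohort. Real
neuropsychological data is noisier and less block-structured than
this; passing the validation floors on the preset demonstrates that
the pipeline is correct and stable under the planted structure, not
that real cohorts will cluster this cleanly.

What the generator does **not** emulate: item-level test scores,
rater disagreement in the visual scales, informative missingness,
correlated residuals across cognitive domains beyond the subtype
structure, and comorbidity-driven atypical profiles.

## Problem sizes and determinism

Validation runs use the generator's native cohort size (n_pd = 81),
100 stability restarts, 100 bootstrap iterations, and oracle suites of
100 randomized small instances — the sizes at which the reference
quantities are defined. Every stochastic routine takes an explicit
seed (NumPy `default_rng`); a fixed config + seed reproduces a cohort
bit-for-bit, and CSV/YAML round-trips are lossless.

## Known limitations

- The constrained solution depends on δ only through initialization;
  very small δ can merge mirror-pair subtypes before refinement
  separates them.
- The pooled (shared) within-cluster covariance assumes comparable
  cluster shapes; per-cluster covariances are not estimable at
  single-digit cluster sizes.
- With a multinomially drawn cohort a rare subtype can receive < 2
  members, in which case its one-vs-rest AUC is undefined and it is
  skipped by the validation report.
- LOOCV AUC's null bias (above) makes cross-subtype AUC comparisons at
  very different class sizes imperfect.
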