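# anatocog

Anatomo-cognitive subtyping of early Parkinson's disease (PD) from
neuropsychological scores and ordinal visual MRI atrophy ratings.

Cognitive impairment in early PD is heterogeneous: executive,
visuospatial, memory and language deficits occur in different mixtures,
reflecting spatially divergent cortical and subcortical degeneration.
`anatocog` implements a classification pipeline for clinicians and
methods researchers that maps each patient's cognitive profile and
regional atrophy — assessed with quick visual rating scales (Scheltens
MTA 0–4, Koedam posterior atrophy 0–3, GCA-frontal 0–3, and the Harper
orbitofrontal / anterior cingulate / frontoinsular scales 0–3, rated per
hemisphere) — onto one of eight theory-derived subtypes:

> cognitively intact · left/right frontosubcortical · left/right
> posterior · left/right hippocampal · global

## Method

The clustering feature space is **x** = (5 cognitive-domain z-scores,
12 standardized atrophy ratings). A correspondence matrix
C ∈ {−1, 0, +1}^(8×17) encodes each subtype's expected signature
(deficit = −1, atrophy = +1; the intact row is zero; left/right rows are
hemisphere mirror images). Scaled by a magnitude δ, its rows become
theoretical centroids **m**_k = δ·C_k that seed standard Lloyd k-means;
labels inherit the seeding row's name, so refined clusters keep their
anatomical meaning. Participants with Mahalanobis distance
d_i = √((x_i − m_k)ᵀ Σ⁻¹ (x_i − m_k)) beyond the cohort mean + 1 SD
(pooled within-cluster Σ, shrunk toward its diagonal) are flagged
*atypical* but retained. Validity is quantified by the mean silhouette,
the Dunn index, the mean adjusted Rand index (ARI) of 100 k-means++
restarts against the constrained partition, and one-vs-rest
leave-one-out cross-validated ROC/AUC per subtype.

Around this core the package provides the full supporting analysis
stack: normality-gated Welch-t / Mann-Whitney comparisons, chi-square
tests, pooled-SD Cohen's d with CI (all computable from printed summary
statistics), MANOVA over the 12 ratings, Pearson/partial correlations
with Bonferroni/FDR control, standardized regressions with residual
diagnostics, nested-CV LASSO with 100-bootstrap stability selection
(robust ⇔ selection frequency ≥ 0.80 and mean |β| > 0.25), and a
synthetic-cohort generator (81 PD + 20 controls) whose ordinal ratings
arise from latent-Gaussian thresholding.

## Worked example

```bash
anatocog generate --delta 1.5 --seed 17 --out cohort.csv
anatocog subtype --cohort cohort.csv --delta 1.5 --seed 17 --out assignments.csv
```

prints the recovered subtype distribution and validity metrics:

```
                          n  percent
cognitively_intact       34     42.0
left_frontosubcortical   12     14.8
right_frontosubcortical  15     18.5
left_posterior            7      8.6
right_posterior           3      3.7
left_hippocampal          6      7.4
right_hippocampal         1      1.2
global                    3      3.7
mean silhouette: 0.534
Dunn index: 0.524
mean ARI over 100 k-means++ restarts: 0.904
atypical: 11 of 81
```

The cohort was planted at reference proportions (40.7% intact, …) with
strong separation (δ = 1.5); the recovered distribution matches up to
multinomial sampling noise, the silhouette of 0.53 indicates moderately
well-separated clusters, the ARI of 0.90 says random-restart k-means
reproduces the constrained partition almost exactly, and 11 of 81
participants sit atypically far (Mahalanobis mean + 1 SD) from their
centroid. The same run from Python:

```python
from anatocog import generate_cohort, paper_like_config, run_subtyping

cohort = generate_cohort(paper_like_config(delta=1.5, seed=17))
result = run_subtyping(cohort, delta=1.5, seed=17)
print(result["validation"].mean_silhouette)   # 0.534
```

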