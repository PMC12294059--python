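"""Constrained subtyping: correspondence matrix, Lloyd refinement,
Mahalanobis atypicality, validity metrics, distribution tables."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from anatocog import (
    ATROPHY_COLUMNS,
    COGNITIVE_DOMAINS,
    SUBTYPES,
    CorrespondenceMatrix,
    constrained_kmeans,
    internal_validity,
    mahalanobis_atypicality,
    stability_ari,
    subtype_distribution,
    theoretical_centroids,
)
from anatocog.subtyping import CLUSTER_FEATURES, dunn_index


class TestCorrespondenceMatrix:
    def test_default_satisfies_invariants(self):
        cm = CorrespondenceMatrix.default()
        assert (cm.frame.loc["cognitively_intact"] == 0).all()
        assert (cm.frame.loc["global", list(ATROPHY_COLUMNS)] == 1).all()

    def test_intact_row_must_be_zero(self):
        frame = CorrespondenceMatrix.default().frame.copy()
        frame.loc["cognitively_intact", "memory"] = -1
        with pytest.raises(ValueError, match="intact"):
            CorrespondenceMatrix(frame)

    def test_hemisphere_mirror_enforced(self):
        frame = CorrespondenceMatrix.default().frame.copy()
        frame.loc["left_hippocampal", "mta_right"] = 1
        with pytest.raises(ValueError, match="mirror"):
            CorrespondenceMatrix(frame)

    def test_csv_round_trip(self, tmp_path):
        cm = CorrespondenceMatrix.default()
        path = tmp_path / "cm.csv"
        cm.to_csv(path)
        assert CorrespondenceMatrix.from_csv(path).frame.equals(cm.frame)


class TestTheoreticalCentroids:
    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            theoretical_centroids(CorrespondenceMatrix.default(), delta=0.0)

    def test_left_hippocampal_support(self):
        cents = theoretical_centroids(CorrespondenceMatrix.default(), 1.0)
        row = cents[SUBTYPES.index("left_hippocampal")]
        nonzero = {CLUSTER_FEATURES[j] for j in np.flatnonzero(row)}
        assert nonzero == {"memory", "mta_left"}
        assert row[CLUSTER_FEATURES.index("memory")] == -1.0
        assert row[CLUSTER_FEATURES.index("mta_left")] == 1.0

    def test_hemisphere_swap_maps_left_onto_right(self):
        cents = theoretical_centroids(CorrespondenceMatrix.default(), 1.3)
        swap = [CLUSTER_FEATURES.index(
            c.replace("_left", "_TMP").replace("_right", "_left")
             .replace("_TMP", "_right")) for c in CLUSTER_FEATURES]
        for left in ("left_posterior", "left_hippocampal",
                     "left_frontosubcortical"):
            right = left.replace("left_", "right_")
            assert np.array_equal(cents[SUBTYPES.index(left)][swap],
                                  cents[SUBTYPES.index(right)])

    def test_intact_centroid_at_origin(self):
        cents = theoretical_centroids(CorrespondenceMatrix.default(), 2.0)
        assert np.all(cents[SUBTYPES.index("cognitively_intact")] == 0)


class TestConstrainedKmeans:
    def test_exact_seed_copies_are_a_fixed_point(self):
        seeds = np.eye(8, 17) * 3.0
        X = np.repeat(seeds, 3, axis=0)
        assignments, cents, objective = constrained_kmeans(X, seeds)
        labels = [a.subtype for a in assignments]
        assert labels == [SUBTYPES[j] for j in np.repeat(np.arange(8), 3)]
        assert np.allclose(cents, seeds)
        assert objective[-1] == pytest.approx(0.0)

    def test_lloyd_objective_non_increasing(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(60, 5))
            seeds = r.normal(size=(8, 5))
            _, _, objective = constrained_kmeans(X, seeds)
            assert np.all(np.diff(objective) <= 1e-9)

    def test_large_delta_equals_nearest_seed_classification(self, rng):
        # data exactly matching widely separated seeds converges in one step
        seeds = rng.normal(size=(8, 6)) * 50
        idx = rng.integers(0, 8, size=40)
        X = seeds[idx] + rng.normal(scale=0.1, size=(40, 6))
        assignments, _, _ = constrained_kmeans(X, seeds)
        nearest = ((X[:, None, :] - seeds[None]) ** 2).sum(-1).argmin(1)
        assert [a.subtype for a in assignments] == [SUBTYPES[j] for j in nearest]
        assert np.array_equal(nearest, idx)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            constrained_kmeans(rng.normal(size=(5, 3)), rng.normal(size=(8, 3)))


class TestMahalanobis:
    def test_point_at_centroid_has_zero_distance(self, rng):
        X = rng.normal(size=(40, 4))
        seeds = rng.normal(size=(8, 4)) * 10
        assignments, cents, _ = constrained_kmeans(X, seeds)
        X2 = X.copy()
        lab0 = SUBTYPES.index(assignments[0].subtype)
        X2[0] = cents[lab0]
        out = mahalanobis_atypicality(assignments, X2, cents)
        assert out[0].distance == pytest.approx(0.0, abs=1e-10)
        assert not out[0].atypical

    def test_identity_covariance_reduces_to_euclidean(self):
        # one cluster at the origin; residual rows crafted so the pooled
        # covariance is exactly the identity (df = n - 1 = 5)
        s2 = np.sqrt(2.0)
        X = np.array([[1, 0], [s2, 0], [-s2, 0],
                      [0, 1], [0, s2], [0, -s2]], dtype=float)
        cents = np.zeros((1, 2))
        from anatocog.subtyping import SubtypeAssignment
        assignments = [SubtypeAssignment(str(i), "cluster_0") for i in range(6)]
        out = mahalanobis_atypicality(assignments, X, cents, shrinkage=0.0)
        assert out[0].distance == pytest.approx(1.0)
        assert out[1].distance == pytest.approx(s2)

    def test_matches_direct_solve_oracle(self):
        from anatocog.subtyping import SubtypeAssignment, _pooled_within_covariance
        for seed in range(100):
            r = np.random.default_rng(seed)
            X = r.normal(size=(30, 5))
            seeds = r.normal(size=(8, 5)) * 4
            assignments, cents, _ = constrained_kmeans(X, seeds)
            labels = np.array([SUBTYPES.index(a.subtype) for a in assignments])
            out = mahalanobis_atypicality(assignments, X, cents, shrinkage=0.1)
            S = _pooled_within_covariance(X, labels, cents, 0.1)
            Sinv = np.linalg.inv(S)
            for i in (0, len(X) - 1):
                d = X[i] - cents[labels[i]]
                expected = np.sqrt(d @ Sinv @ d)
                assert out[i].distance == pytest.approx(expected, rel=1e-8)

    def test_policies_differ_and_flagged_keep_labels(self, preset_result):
        frame = pd.DataFrame([(a.subtype, a.atypical)
                              for a in preset_result["assignments"]],
                             columns=["subtype", "atypical"])
        # atypical participants keep a subtype label
        assert frame["subtype"].notna().all()
        assert 0 < frame["atypical"].sum() < len(frame)

    def test_unknown_policy_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        seeds = rng.normal(size=(8, 3))
        assignments, cents, _ = constrained_kmeans(X, seeds)
        with pytest.raises(ValueError, match="policy"):
            mahalanobis_atypicality(assignments, X, cents, policy="bogus")


class TestStabilityAri:
    def test_perfect_separation_gives_unit_ari(self, rng):
        cents = np.eye(8, 10) * 60
        idx = np.repeat(np.arange(8), 6)
        X = cents[idx] + rng.normal(scale=0.05, size=(48, 10))
        labels = [SUBTYPES[j] for j in idx]
        aris, mean = stability_ari(X, labels, n_iter=20, seed=0)
        assert mean == pytest.approx(1.0)

    def test_ari_label_permutation_invariance(self, rng):
        labels = rng.integers(0, 8, size=81)
        perm = rng.permutation(8)
        assert adjusted_rand_score(labels, perm[labels]) == pytest.approx(1.0)

    def test_independent_partitions_near_zero(self):
        r = np.random.default_rng(0)
        vals = [adjusted_rand_score(r.integers(0, 8, 81), r.integers(0, 8, 81))
                for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.05


class TestInternalValidity:
    def test_separated_masses(self, rng):
        X = np.vstack([rng.normal(0, 0.01, size=(20, 3)),
                       rng.normal(10, 0.01, size=(20, 3))])
        labels = ["a"] * 20 + ["b"] * 20
        val = internal_validity(X, labels)
        assert val.mean_silhouette > 0.99
        assert val.dunn_index > 100

    def test_identical_points_silhouette_zero_by_convention(self):
        X = np.ones((10, 3))
        val = internal_validity(X, ["a"] * 5 + ["b"] * 5)
        assert val.mean_silhouette == 0.0

    def test_silhouette_matches_brute_force(self):
        def brute_silhouette(X, labels):
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            labels = np.asarray(labels)
            vals = []
            for i in range(len(X)):
                same = (labels == labels[i])
                if same.sum() == 1:
                    vals.append(0.0)
                    continue
                a = D[i, same].sum() / (same.sum() - 1)
                b = min(D[i, labels == c].mean()
                        for c in set(labels) if c != labels[i])
                vals.append((b - a) / max(a, b))
            return float(np.mean(vals))

        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(10, 50))
            X = r.normal(size=(n, 3))
            labels = r.integers(0, 3, size=n)
            if len(set(labels.tolist())) < 2:
                continue
            ours = internal_validity(X, [str(c) for c in labels]).mean_silhouette
            assert ours == pytest.approx(brute_silhouette(X, labels), abs=1e-10)

    def test_dunn_definition_on_crafted_clusters(self):
        X = np.array([[0.0, 0], [1, 0], [10, 0], [10, 2]])
        labels = np.array([0, 0, 1, 1])
        # min separation = |(1,0)-(10,0)| = 9; max diameter = 2
        assert dunn_index(X, labels) == pytest.approx(9 / 2)


class TestSubtypeDistribution:
    def test_reference_counts_round_to_published_percentages(self):
        counts = (33, 10, 9, 7, 6, 5, 4, 7)
        labels = [s for s, c in zip(SUBTYPES, counts) for _ in range(c)]
        dist = subtype_distribution(labels)
        assert list(dist["n"]) == list(counts)
        assert list(dist["percent"]) == [40.7, 12.3, 11.1, 8.6, 7.4, 6.2,
                                         4.9, 8.6]

    def test_atypical_fraction_rounds_as_published(self):
        labels = ["atypical"] * 7 + ["typical"] * 74
        dist = subtype_distribution(labels)
        assert dist.loc["atypical", "percent"] == 8.6

    def test_single_subtype(self):
        dist = subtype_distribution(["global"] * 12)
        assert dist.loc["global", "percent"] == 100.0

    def test_percentages_sum_to_hundred(self, preset_result):
        dist = preset_result["distribution"]
        assert dist["percent"].sum() == pytest.approx(100.0, abs=0.3)


class TestEndToEnd:
    def test_label_recovery_on_strong_separation(self, preset_cohort,
                                                 preset_result):
        true = preset_cohort.pd_rows()["true_subtype"].tolist()
        pred = [a.subtype for a in preset_result["assignments"]]
        assert adjusted_rand_score(true, pred) >= 0.8

    def test_recovered_proportions_near_planted(self, preset_result):
        dist = preset_result["distribution"]
        planted = dict(zip(SUBTYPES, (33, 10, 9, 7, 6, 5, 4, 7)))
        # multinomial draw + clustering: within a loose envelope
        for s in SUBTYPES:
            assert abs(int(dist.loc[s, "n"]) - planted[s]) <= 8
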