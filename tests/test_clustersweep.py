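"""Scaling, PAM, Lance-Williams agglomeration, FM index, sweep, and stump."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from belugabuzz.clustersweep import (
    ClusterConfig,
    agglomerate,
    enumerate_configs,
    fit_stump,
    fowlkes_mallows,
    hierarchical_cluster,
    pam_brute_force,
    pam_cluster,
    run_sweep,
    scale_features,
    sweep_report,
    _distance_matrix,
    _pam_cost,
)
from belugabuzz.errors import ConfigError, DegenerateScalingError, NoSplitError


def same_partition(a, b) -> bool:
    return fowlkes_mallows(a, b) == 1.0


class TestScaleFeatures:
    def test_unit_column(self):
        out = scale_features(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1, 0, 1])

    def test_zero_variance_column_named(self):
        frame = pd.DataFrame({"minICI": [1.0, 2.0, 3.0], "slope": [5.0, 5.0, 5.0]})
        with pytest.raises(DegenerateScalingError, match="slope"):
            scale_features(frame)

    def test_output_moments(self):
        rng = np.random.default_rng(3)
        out = scale_features(rng.normal(2.0, 7.0, size=(40, 4)))
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1, atol=1e-12)


class TestPam:
    def test_separated_pairs(self):
        labels = pam_cluster(np.array([0.0, 0.1, 10.0, 10.1]))
        assert same_partition(labels, [0, 0, 1, 1])

    @pytest.mark.parametrize("distance", ["euclidean", "squared_euclidean", "manhattan"])
    def test_local_optimality(self, distance):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n = int(rng.integers(4, 10))
            X = rng.normal(size=(n, 2))
            labels = pam_cluster(X, distance)
            D = _distance_matrix(X, distance)
            # recover the realized cost: medoid of each cluster minimizes
            # within-cluster dissimilarity under the assignment actually used
            meds = []
            for c in (0, 1):
                idx = np.nonzero(labels == c)[0]
                meds.append(idx[np.argmin(D[np.ix_(idx, idx)].sum(axis=1))])
            cost = _pam_cost(D, meds)
            for mi in range(2):
                for h in range(n):
                    if h in meds:
                        continue
                    trial = list(meds)
                    trial[mi] = h
                    assert _pam_cost(D, trial) >= cost - 1e-9

    def test_fixed_instance_matches_exhaustive_search(self):
        # frozen via the brute-force oracle over all C(6,2) medoid pairs
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 2))
        labels = pam_cluster(X, "euclidean")
        medoids, cost = pam_brute_force(X, "euclidean")
        D = _distance_matrix(X, "euclidean")
        assert same_partition(labels, np.argmin(D[:, list(medoids)], axis=1))

    def test_duplicated_points_deterministic(self):
        X = np.array([[1.0, 1.0]] * 4 + [[5.0, 5.0]] * 2)
        a = pam_cluster(X)
        b = pam_cluster(X)
        np.testing.assert_array_equal(a, b)
        assert same_partition(a, [0, 0, 0, 0, 1, 1])

    def test_one_dimensional_euclidean_equals_manhattan(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(4, 12)))
            np.testing.assert_array_equal(
                pam_cluster(x, "euclidean"), pam_cluster(x, "manhattan")
            )

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            pam_cluster(np.array([[1.0]]), k=2)


class TestHierarchical:
    def test_collinear_single_linkage(self):
        labels = hierarchical_cluster(np.array([0.0, 1.0, 10.0]), "euclidean", "single")
        assert same_partition(labels, [0, 0, 1])

    @pytest.mark.parametrize(
        "ours, scipy_method",
        [
            ("single", "single"),
            ("complete", "complete"),
            ("average", "average"),
            ("weighted_average", "weighted"),
        ],
    )
    @pytest.mark.parametrize("distance", ["euclidean", "manhattan"])
    def test_lance_williams_matches_scipy_on_given_distances(
        self, ours, scipy_method, distance
    ):
        rng = np.random.default_rng(17)
        for _ in range(5):
            X = rng.normal(size=(10, 3))
            d = pdist(X, "euclidean" if distance == "euclidean" else "cityblock")
            labels = hierarchical_cluster(X, distance, ours)
            ref = fcluster(linkage(d, scipy_method), 2, "maxclust")
            assert same_partition(labels, ref)

    def test_centroid_matches_feature_space_recomputation(self):
        # centroid linkage on squared Euclidean distances must merge the
        # clusters whose centroids are closest, recomputed from scratch
        rng = np.random.default_rng(23)
        X = rng.normal(size=(9, 2))
        dendro = agglomerate(_distance_matrix(X, "squared_euclidean"), "centroid")
        members = {i: [i] for i in range(len(X))}
        for m, (a, b, h) in enumerate(dendro.merges):
            ca = X[members[a]].mean(axis=0)
            cb = X[members[b]].mean(axis=0)
            assert h == pytest.approx(float(((ca - cb) ** 2).sum()), rel=1e-9)
            members[len(X) + m] = members.pop(a) + members.pop(b)

    def test_ward_recovers_separated_blobs(self):
        rng = np.random.default_rng(29)
        X = np.vstack(
            [rng.normal(0, 0.3, size=(12, 2)), rng.normal(6, 0.3, size=(12, 2))]
        )
        labels = hierarchical_cluster(X, "euclidean", "ward")
        assert same_partition(labels, [0] * 12 + [1] * 12)

    def test_invalid_pairing_rejected(self):
        with pytest.raises(ConfigError):
            hierarchical_cluster(np.zeros((4, 2)), "euclidean", "centroid")
        with pytest.raises(ConfigError):
            hierarchical_cluster(np.zeros((4, 2)), "manhattan", "ward")

    def test_newick_export_parses(self):
        X = np.array([0.0, 1.0, 10.0])
        _, tree = hierarchical_cluster(
            X, "euclidean", "single", return_tree=True
        )
        text = tree.to_newick(["a", "b", "c"])
        assert text.endswith(";") and text.count("(") == 2
        for name in ("a", "b", "c"):
            assert name in text


class TestFowlkesMallows:
    def test_perfect_agreement(self):
        assert fowlkes_mallows([0, 0, 1, 1], ["x", "x", "y", "y"]) == 1.0

    def test_hand_count_zero(self):
        # T=0 co-clustered pairs in both, P=Q=2
        assert fowlkes_mallows([1, 2, 1, 2], ["A", "A", "B", "B"]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fowlkes_mallows([1, 2], [1, 2, 3])

    def test_matches_direct_pair_counting(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(3, 25))
            a = rng.integers(0, 3, n)
            b = rng.integers(0, 3, n)
            T = P = Q = 0
            for i, j in itertools.combinations(range(n), 2):
                sa, sb = a[i] == a[j], b[i] == b[j]
                P += sa
                Q += sb
                T += sa and sb
            expected = T / np.sqrt(P * Q) if P and Q else 0.0
            assert fowlkes_mallows(a, b) == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= fowlkes_mallows(a, b) <= 1.0


class TestSweep:
    def test_grid_cardinality_and_restrictions(self):
        configs = enumerate_configs()
        pam = [c for c in configs if c.family == "pam"]
        hier = [c for c in configs if c.family == "hierarchical"]
        assert len(pam) == 16 and len(hier) == 48
        for c in hier:
            if c.linkage == "centroid":
                assert c.distance == "squared_euclidean"
            if c.linkage == "median":
                assert c.distance == "euclidean"
            if c.linkage == "ward":
                assert c.distance in ("euclidean", "squared_euclidean")

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            ClusterConfig("hierarchical", "manhattan", "centroid", ("minICI",), False)
        with pytest.raises(ConfigError):
            ClusterConfig("pam", "euclidean", None, ("minICI",), False, k=3)

    def test_sweep_on_separable_fixture(self, buzz_dataset):
        _, features = buzz_dataset
        labels = features["context"].to_numpy()
        results = run_sweep(features, labels)
        assert len(results) == 64
        # minICI and ICIir have non-overlapping ranges by construction, so
        # ward/euclidean/unscaled on that variable pair separates perfectly
        # (the other three variables overlap between behaviors and carry no
        # such guarantee)
        ward_2var = [
            r
            for r in results
            if r.config.linkage == "ward"
            and r.config.distance == "euclidean"
            and not r.config.scaled
            and r.config.variables == ("minICI", "ICIir")
        ]
        assert len(ward_2var) == 1
        assert ward_2var[0].fm_index == 1.0
        assert results[0].fm_index == 1.0  # top of the ranking is perfect
        # sorted descending
        scores = [r.fm_index for r in results]
        assert scores == sorted(scores, reverse=True)
        report = sweep_report(results)
        assert list(report.columns) == [
            "family",
            "distance",
            "linkage",
            "variables",
            "scaled",
            "fm_index",
        ]

    def test_missing_variable_column(self):
        with pytest.raises(ValueError, match="ICIir"):
            run_sweep(pd.DataFrame({"minICI": [1.0, 2.0]}), [0, 1])


class TestStump:
    def test_midpoint_between_adjacent_class_extremes(self):
        feeding = [2.3, 5.0, 7.1, 8.92]
        social = [9.03, 12.0, 20.0, 29.75]
        frame = pd.DataFrame({"minICI": feeding + social})
        y = [0] * 4 + [1] * 4
        rule = fit_stump(frame, y, ["minICI"])
        assert rule.threshold == pytest.approx((8.92 + 9.03) / 2)
        assert rule.impurity == 0.0
        assert rule.below_class == 0 and rule.above_class == 1

    def test_perfect_separator_beats_imperfect(self):
        frame = pd.DataFrame(
            {"noisy": [1.0, 3.0, 2.0, 4.0], "clean": [0.0, 0.1, 5.0, 5.1]}
        )
        y = [0, 0, 1, 1]
        rule = fit_stump(frame, y, ["noisy", "clean"])
        assert rule.variable == "clean"

    def test_variable_order_breaks_ties(self):
        frame = pd.DataFrame(
            {"minICI": [1.0, 2.0, 8.0, 9.0], "ICIir": [-3.0, -2.0, 4.0, 5.0]}
        )
        y = [0, 0, 1, 1]
        assert fit_stump(frame, y, ["minICI", "ICIir"]).variable == "minICI"
        assert fit_stump(frame, y, ["ICIir", "minICI"]).variable == "ICIir"

    def test_single_class_rejected(self):
        with pytest.raises(NoSplitError):
            fit_stump(pd.DataFrame({"minICI": [1.0, 2.0]}), [0, 0], ["minICI"])

    def test_separable_one_dimensional_always_pure(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            a = rng.uniform(0, 1, size=6)
            b = rng.uniform(2, 3, size=5)
            frame = pd.DataFrame({"x": np.concatenate([a, b])})
            rule = fit_stump(frame, [0] * 6 + [1] * 5, ["x"])
            assert rule.impurity == 0.0
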