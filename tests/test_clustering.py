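"""Segment averaging, Davies-Bouldin evaluation and Sammon embedding."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import davies_bouldin_score

from ssrsa.clustering import (
    LabelScheme,
    SegmentTable,
    davies_bouldin,
    db_permutation_p,
    default_label_schemes,
    evaluate_all_schemes,
    sammon_embed,
    segment_average,
)
from ssrsa.core import ConditionSet
from ssrsa.model_rdms import FeatureTimeline
from ssrsa.synthetic import SynthConfig, make_conditions, make_layer_activations, make_segments


def naive_davies_bouldin(points, labels):
    """Independent double-loop reference implementation."""
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    centroids, scatters = [], []
    for lab in uniq:
        members = points[labels == lab]
        c = members.mean(axis=0)
        centroids.append(c)
        scatters.append(np.mean([np.linalg.norm(m - c) for m in members]))
    total = 0.0
    for i in range(len(uniq)):
        worst = -np.inf
        for j in range(len(uniq)):
            if i == j:
                continue
            d = np.linalg.norm(np.array(centroids[i]) - np.array(centroids[j]))
            worst = max(worst, (scatters[i] + scatters[j]) / d)
        total += worst
    return total / len(uniq)


def segments_df(rows):
    return SegmentTable(
        pd.DataFrame(rows, columns=["condition", "start_ms", "end_ms", "phone"])
    )


class TestSegmentTable:
    def test_rejects_overlap_and_inverted_segments(self):
        with pytest.raises(ValueError, match="overlap"):
            segments_df([("w0", 0, 50, "b"), ("w0", 40, 80, "a")])
        with pytest.raises(ValueError, match="exceed"):
            segments_df([("w0", 50, 50, "b")])


class TestSegmentAverage:
    def make_timeline(self, frames_per_cond):
        conds = ConditionSet(
            tuple(frames_per_cond), tuple(10.0 * (len(f) - 1) + 25.0 for f in frames_per_cond.values())
        )
        return FeatureTimeline(
            conditions=conds,
            layer_name="L7",
            frames=tuple(np.asarray(f, dtype=float) for f in frames_per_cond.values()),
        )

    def test_single_frame_segment_returns_that_frame(self):
        tl = self.make_timeline({"w0": [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]})
        # frame midpoints: 12.5, 22.5, 32.5; segment [20, 30) holds frame 1
        sv = segment_average(tl, segments_df([("w0", 20, 30, "b")]))
        np.testing.assert_array_equal(sv.vectors, [[3.0, 4.0]])

    def test_repeated_phone_yields_separate_vectors(self):
        tl = self.make_timeline({"w0": [[0.0], [1.0], [2.0], [3.0], [4.0]]})
        sv = segment_average(
            tl, segments_df([("w0", 0, 30, "b"), ("w0", 30, 65, "b")])
        )
        assert len(sv.vectors) == 2
        assert not np.array_equal(sv.vectors[0], sv.vectors[1])
        assert list(sv.table["phone"]) == ["b", "b"]

    def test_three_frame_segment_is_arithmetic_mean(self):
        tl = self.make_timeline({"w0": [[0.0], [3.0], [9.0], [100.0]]})
        # midpoints 12.5, 22.5, 32.5, 42.5; [10, 40) captures first three
        sv = segment_average(tl, segments_df([("w0", 10, 40, "s")]))
        np.testing.assert_allclose(sv.vectors, [[4.0]])

    def test_empty_segment_error_names_the_segment(self):
        tl = self.make_timeline({"w0": [[0.0], [1.0], [2.0]]})
        with pytest.raises(ValueError, match=r"w0.*\[0, 10.*'p'"):
            segment_average(tl, segments_df([("w0", 0, 10, "p")]))


class TestDaviesBouldin:
    def test_duplicated_identical_points_give_zero(self):
        points = np.array([[0.0, 0]] * 4 + [[5.0, 5]] * 4)
        labels = ["a"] * 4 + ["b"] * 4
        assert davies_bouldin(points, labels) == 0.0

    def test_hand_example_quarter(self):
        points = np.array([[0.0], [1.0], [4.0], [5.0]])
        labels = ["a", "a", "b", "b"]
        assert davies_bouldin(points, labels) == pytest.approx(0.25)

    def test_invariant_to_point_order(self, rng):
        points = rng.normal(size=(30, 4))
        labels = rng.integers(0, 3, size=30)
        perm = rng.permutation(30)
        assert davies_bouldin(points, labels) == pytest.approx(
            davies_bouldin(points[perm], labels[perm])
        )

    def test_matches_naive_reference_exactly(self, rng):
        for _ in range(20):
            k = rng.integers(2, 5)
            points = rng.normal(size=(25, 3))
            labels = rng.integers(0, k, size=25)
            if len(set(labels.tolist())) < 2:
                continue
            assert davies_bouldin(points, labels) == pytest.approx(
                naive_davies_bouldin(points, labels), rel=1e-12
            )

    def test_matches_sklearn(self, rng):
        points = rng.normal(size=(40, 5))
        labels = rng.integers(0, 4, size=40)
        assert davies_bouldin(points, labels) == pytest.approx(
            davies_bouldin_score(points, labels)
        )

    def test_rigid_motion_and_scale_invariance(self, rng):
        points = rng.normal(size=(20, 3))
        labels = rng.integers(0, 3, size=20)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = 3.7 * points @ q.T + rng.normal(size=3)
        assert davies_bouldin(points, labels) == pytest.approx(
            davies_bouldin(moved, labels)
        )

    def test_single_label_and_coincident_centroids_error(self):
        with pytest.raises(ValueError, match="2 distinct"):
            davies_bouldin(np.zeros((4, 2)), ["a"] * 4)
        points = np.array([[1.0, 0], [-1.0, 0], [0.0, 1], [0.0, -1]])
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin(points, ["a", "a", "b", "b"])


class TestDbPermutationP:
    def test_perfect_clusters_give_minimum_p(self):
        points = np.array([[0.0, 0]] * 5 + [[4.0, 4]] * 5)
        labels = ["a"] * 5 + ["b"] * 5
        obs, p = db_permutation_p(points, labels, n_perm=500, seed=1)
        assert obs == 0.0
        assert p == pytest.approx(1 / 500)

    def test_structureless_labels_give_uniformish_p(self, rng):
        # coarse calibration: p-values under the null are roughly uniform
        ps = []
        for i in range(40):
            r = np.random.default_rng(100 + i)
            points = r.normal(size=(18, 3))
            labels = r.integers(0, 3, size=18)
            if len(set(labels.tolist())) < 2:
                continue
            _, p = db_permutation_p(points, labels, n_perm=99, seed=i)
            ps.append(p)
        ps = np.array(ps)
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.1).mean() < 0.3

    def test_observed_worst_clamps_to_one(self):
        # labels split one tight cloud: observed index is huge, nulls can tie
        points = np.vstack([np.eye(3), 2 * np.eye(3)])
        labels = ["a", "b", "a", "b", "a", "b"]
        _, p = db_permutation_p(points, labels, n_perm=50, seed=0)
        assert p <= 1.0


class TestEvaluateAllSchemes:
    def test_planted_feature_layer_beats_noise_layer(self):
        cfg = SynthConfig(
            n_conditions=10,
            layer_dims={"planted": 16, "noise": 16},
            cluster_separation=4.0,
            seed=2,
        )
        conds = make_conditions(cfg)
        obstruents = ("p", "t", "k", "s", "f", "b", "d", "g")
        segments = make_segments(cfg, conds, phones=obstruents)
        place = default_label_schemes()["place"]
        planted = make_layer_activations(cfg, segments, scheme=place, conditions=conds)["planted"]
        noise_cfg = SynthConfig(
            n_conditions=10,
            layer_dims={"noise": 16},
            cluster_separation=0.0,
            seed=3,
        )
        noise = make_layer_activations(noise_cfg, segments, scheme=place, conditions=conds)["noise"]
        table = evaluate_all_schemes(
            {"planted": planted, "noise": noise},
            segments,
            {"place": place},
            n_perm=200,
            seed=0,
        )
        by_layer = table.set_index("layer")
        assert by_layer.loc["planted", "db_index"] < by_layer.loc["noise", "db_index"]
        assert by_layer.loc["planted", "p_value"] <= 0.01

    def test_two_phone_scheme_is_valid(self):
        cfg = SynthConfig(n_conditions=6, layer_dims={"L7": 8}, seed=4)
        conds = make_conditions(cfg)
        segments = make_segments(cfg, conds, phones=("p", "s"))
        tl = make_layer_activations(cfg, segments, conditions=conds)["L7"]
        table = evaluate_all_schemes(
            {"L7": tl}, segments, {"phone": LabelScheme.phone_scheme(("p", "s"))},
            n_perm=100, seed=0,
        )
        assert table.loc[0, "n_labels"] == 2
        assert np.isfinite(table.loc[0, "db_index"])

    def test_inapplicable_scheme_is_flagged_not_scored(self):
        cfg = SynthConfig(n_conditions=6, layer_dims={"L7": 8}, seed=4)
        conds = make_conditions(cfg)
        segments = make_segments(cfg, conds, phones=("p", "s"))  # no vowels
        tl = make_layer_activations(cfg, segments, conditions=conds)["L7"]
        table = evaluate_all_schemes(
            {"L7": tl}, segments, {"closeness": default_label_schemes()["closeness"]},
            n_perm=100, seed=0,
        )
        assert np.isnan(table.loc[0, "db_index"])
        assert "fewer than 2 labels" in table.loc[0, "note"]


class TestSammon:
    def test_planar_configuration_embeds_with_near_zero_stress(self, rng):
        pts = rng.normal(size=(8, 2))
        D = squareform(pdist(pts))
        result = sammon_embed(D, seed=1, max_iter=800)
        assert result.stress < 1e-4

    def test_metric_triangle_embeds_exactly(self):
        D = np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]])
        result = sammon_embed(D, seed=0, max_iter=800)
        assert result.stress < 1e-6

    def test_regular_tetrahedron_has_positive_stress_in_2d(self):
        D = np.ones((4, 4)) - np.eye(4)
        result = sammon_embed(D, seed=0, max_iter=800)
        assert result.stress > 1e-4  # cannot embed a regular 3-simplex in the plane

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(6, 3))
        D = squareform(pdist(pts))
        a = sammon_embed(D, seed=5)
        b = sammon_embed(D, seed=5)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert a.stress == b.stress

    def test_zero_off_diagonal_distance_is_an_error(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = 1.0
        with pytest.raises(ValueError, match="strictly positive"):
            sammon_embed(D)
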