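import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pistack import selection as sel


def make_table(scores, ids=None):
    ids = ids or [f"p{i:05d}" for i in range(len(scores))]
    return pd.DataFrame({"pair_id": ids, "score": scores})


class TestFlagInliers:
    def test_threshold_one_strict_bound_empty(self):
        table = make_table([1.0, 0.9, 1.0])
        assert len(sel.flag_inliers(table, threshold=1.0)) == 0

    def test_threshold_zero_keeps_all_positive(self):
        table = make_table([0.1, 0.5, 0.9])
        assert len(sel.flag_inliers(table, threshold=0.0)) == 3

    def test_binomial_expectation_uniform_scores(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.uniform(size=10_000))
        n = len(sel.flag_inliers(table, threshold=0.7))
        assert abs(n - 3000) <= 150

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.uniform(size=500))
        once = sel.flag_inliers(table, threshold=0.7)
        pd.testing.assert_frame_equal(sel.flag_inliers(once, threshold=0.7), once)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            sel.flag_inliers(make_table([1.5]), threshold=0.7)


class TestTopQuartile:
    def test_21736_rows_give_5434(self):
        rng = np.random.default_rng(2)
        table = make_table(rng.uniform(size=21_736))
        assert len(sel.top_quartile(table)) == 5434

    def test_four_rows_give_one(self):
        assert len(sel.top_quartile(make_table([0.1, 0.2, 0.3, 0.4]))) == 1

    def test_matches_sort_then_slice_oracle(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=1000)
        table = make_table(scores)
        got = sel.top_quartile(table)
        oracle = table.sort_values(
            ["score", "pair_id"], ascending=[False, True]
        ).head(250)
        pd.testing.assert_frame_equal(got, oracle)

    def test_empty_table(self):
        assert len(sel.top_quartile(make_table([]))) == 0

    def test_nested_application_is_subset(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.uniform(size=400))
        once = sel.top_quartile(table)
        twice = sel.top_quartile(once)
        assert set(twice["pair_id"]) <= set(once["pair_id"])

    def test_deterministic_tie_break(self):
        table = make_table([0.5, 0.5, 0.5, 0.1], ids=["d", "b", "a", "c"])
        got = sel.top_quartile(table)
        assert list(got["pair_id"]) == ["a"]


class TestCoformerPopularity:
    def test_toy_counts(self):
        pairs = pd.DataFrame({"mol_a": ["A", "A"], "mol_b": ["B", "C"]})
        counts = sel.coformer_popularity(pairs)
        assert counts.to_dict() == {"A": 2, "B": 1, "C": 1}
        assert list(counts.index) == ["A", "B", "C"]  # ties broken by id

    def test_empty_subset(self):
        pairs = pd.DataFrame({"mol_a": [], "mol_b": []})
        assert len(sel.coformer_popularity(pairs)) == 0

    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(21, 40)), min_size=1, max_size=60))
    @settings(max_examples=30, deadline=None)
    def test_handshake_identity(self, raw_pairs):
        pairs = pd.DataFrame(
            {"mol_a": [f"m{a}" for a, _ in raw_pairs], "mol_b": [f"m{b}" for _, b in raw_pairs]}
        )
        counts = sel.coformer_popularity(pairs)
        assert counts.sum() == 2 * len(pairs)


def oracle_pareto(points):
    """O(n^2) dominance check."""
    n = len(points)
    front = []
    for i in range(n):
        dominated = False
        for j in range(n):
            if i == j:
                continue
            if (
                points[j][0] >= points[i][0]
                and points[j][1] >= points[i][1]
                and (points[j][0] > points[i][0] or points[j][1] > points[i][1])
            ):
                dominated = True
                break
        if not dominated:
            front.append(i)
    return set(front)


class TestParetoFront:
    def _df(self, pts):
        return pd.DataFrame(pts, columns=["score", "similarity"])

    def test_mutually_nondominated_all_on_front(self):
        res = sel.pareto_front(self._df([(1, 0), (0, 1), (0.5, 0.5)]))
        assert res.table["on_front"].all()

    def test_dominated_point_excluded(self):
        res = sel.pareto_front(self._df([(1, 1), (0.5, 0.5)]))
        assert list(res.table["on_front"]) == [True, False]

    def test_exact_ties_kept_on_front(self):
        res = sel.pareto_front(self._df([(1, 1), (1, 1), (0, 0)]))
        assert list(res.table["on_front"]) == [True, True, False]

    def test_matches_oracle_on_random_points(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(200, 2))
        res = sel.pareto_front(self._df(pts))
        assert set(np.flatnonzero(res.table["on_front"].to_numpy())) == oracle_pareto(pts)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(size=(100, 2))
        base = sel.pareto_front(self._df(pts)).table["on_front"]
        transformed = np.column_stack([np.exp(3 * pts[:, 0]), pts[:, 1] ** 3])
        after = sel.pareto_front(self._df(transformed)).table["on_front"]
        pd.testing.assert_series_equal(base, after)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sel.pareto_front(self._df([(np.nan, 1.0)]))


class TestNearestKnownPairs:
    def test_identical_pair_distance_zero_rank_one(self, rng):
        L = rng.normal(size=(20, 2, 3))
        ids = [f"p{i}" for i in range(20)]
        out = sel.nearest_known_pairs(L[7].ravel(), L, ids, k=5)
        assert out.iloc[0]["pair_id"] == "p7"
        assert out.iloc[0]["distance"] == 0.0

    def test_k_equals_dataset_size_full_sorted_list(self, rng):
        L = rng.normal(size=(10, 2, 3))
        ids = [f"p{i}" for i in range(10)]
        out = sel.nearest_known_pairs(rng.normal(size=6), L, ids, k=10)
        assert len(out) == 10
        assert out["distance"].is_monotonic_increasing

    def test_matches_exhaustive_oracle(self, rng):
        L = rng.normal(size=(50, 2, 4))
        ids = [f"p{i:02d}" for i in range(50)]
        q = rng.normal(size=8)
        out = sel.nearest_known_pairs(q, L, ids, k=50)
        expected = np.minimum(
            np.linalg.norm(L.reshape(50, 8) - q, axis=1),
            np.linalg.norm(L[:, ::-1, :].reshape(50, 8) - q, axis=1),
        )
        order = np.lexsort((np.array(ids), expected))
        np.testing.assert_array_equal(out["pair_id"].to_numpy(), np.array(ids)[order])
        np.testing.assert_allclose(out["distance"].to_numpy(), expected[order])

    def test_orientation_invariance_of_query_result(self, rng):
        L = rng.normal(size=(20, 2, 3))
        ids = [f"p{i}" for i in range(20)]
        q = rng.normal(size=6)
        out1 = sel.nearest_known_pairs(q, L, ids, k=20)
        # flipping labelled orientations must not change distances
        out2 = sel.nearest_known_pairs(q, L[:, ::-1, :], ids, k=20)
        pd.testing.assert_frame_equal(out1, out2)

    def test_k_too_large_warns_and_returns_all(self, rng):
        L = rng.normal(size=(5, 2, 2))
        with pytest.warns(UserWarning, match="exceeds"):
            out = sel.nearest_known_pairs(rng.normal(size=4), L, list("abcde"), k=9)
        assert len(out) == 5


class TestDistancePreservation:
    def test_exact_isometry_scores_one(self, rng):
        X = rng.normal(size=(20, 2))
        assert sel.distance_preservation_score(X, X.copy()) == pytest.approx(1.0)

    def test_rotation_is_isometry(self, rng):
        X = rng.normal(size=(30, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        assert sel.distance_preservation_score(X, X @ R.T) == pytest.approx(1.0)

    def test_shuffled_coordinates_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 5))
        Y = rng.permutation(X[:, :2])
        assert abs(sel.distance_preservation_score(X, Y)) < 0.15

    def test_matches_hand_rolled_pearson(self, rng):
        X = rng.normal(size=(20, 6))
        Y = rng.normal(size=(20, 2))
        dx, dy = [], []
        for i in range(20):
            for j in range(i + 1, 20):
                dx.append(np.linalg.norm(X[i] - X[j]))
                dy.append(np.linalg.norm(Y[i] - Y[j]))
        dx, dy = np.array(dx), np.array(dy)
        assert len(dx) == 190
        r = np.sum((dx - dx.mean()) * (dy - dy.mean())) / (
            np.sqrt(np.sum((dx - dx.mean()) ** 2)) * np.sqrt(np.sum((dy - dy.mean()) ** 2))
        )
        assert sel.distance_preservation_score(X, Y) == pytest.approx(r, abs=1e-12)


def test_embed_2d_qc_smoke():
    # small UMAP run: structure-preserving projection of clustered data
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(size=(30, 6)), rng.normal(size=(30, 6)) + 8.0])
    coords, qc = sel.embed_2d_qc(X, n_neighbors=10, min_dist=0.1, seed=0)
    assert coords.shape == (60, 2)
    assert qc > 0.5


def test_embed_2d_qc_too_few_points():
    with pytest.raises(ValueError, match="n_neighbors"):
        sel.embed_2d_qc(np.zeros((5, 3)), n_neighbors=10)


def test_selection_config_validation():
    with pytest.raises(ValueError):
        sel.SelectionConfig(inlier_threshold=1.4)
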