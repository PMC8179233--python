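import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from pistack import occ_traditional as ot

from conftest import build_pair_matrix


@pytest.fixture(scope="module")
def blob(request):
    """Tight 2-D Gaussian blob + 5 far planted outliers."""
    rng = np.random.default_rng(0)
    inliers = rng.normal(0, 1, size=(200, 2))
    outliers = rng.normal(0, 1, size=(5, 2)) + 25.0
    return inliers, outliers


class TestFitDetector:
    @pytest.mark.parametrize("family", ot.FAMILIES)
    def test_contamination_contract(self, family):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(1000, 4))
        model = ot.fit_detector(ot.DetectorSpec(family=family, contamination=0.05, seed=0), X)
        n_inliers = int(model.is_inlier(X).sum())
        assert abs(n_inliers - 950) <= 1

    def test_identical_rows_knn_all_inliers(self):
        X = np.ones((50, 3))
        model = ot.fit_detector(ot.DetectorSpec(family="knn_distance"), X)
        assert np.all(model.score(X) == 0.0)
        assert model.is_inlier(X).all()

    @pytest.mark.parametrize("family", ot.FAMILIES)
    def test_planted_outliers_score_lowest(self, family, blob):
        inliers, outliers = blob
        model = ot.fit_detector(ot.DetectorSpec(family=family, seed=0), inliers)
        s_in = model.score(inliers)
        s_out = model.score(outliers)
        assert s_out.max() < np.quantile(s_in, 0.05)

    def test_degenerate_input_rejected_for_density_families(self):
        X = np.ones((30, 2))
        for fam in ("gaussian_mixture_density", "local_outlier_factor"):
            with pytest.raises(ValueError, match="degenerate"):
                ot.fit_detector(ot.DetectorSpec(family=fam), X)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown detector family"):
            ot.DetectorSpec(family="kmeans")

    def test_contamination_bounds(self):
        with pytest.raises(ValueError):
            ot.DetectorSpec(family="knn_distance", contamination=0.7)


class TestScore:
    def test_deterministic_rescoring(self, blob):
        inliers, _ = blob
        model = ot.fit_detector(ot.DetectorSpec(family="isolation_forest", seed=3), inliers)
        np.testing.assert_array_equal(model.score(inliers), model.score(inliers))

    @pytest.mark.parametrize("family", ot.FAMILIES)
    def test_center_scores_above_far_point(self, family, blob):
        inliers, _ = blob
        model = ot.fit_detector(ot.DetectorSpec(family=family, seed=0), inliers)
        center = np.zeros((1, 2))
        far = np.full((1, 2), 30.0)
        assert model.score(center)[0] > model.score(far)[0]

    def test_dimension_mismatch_rejected(self, blob):
        inliers, _ = blob
        model = ot.fit_detector(ot.DetectorSpec(family="knn_distance"), inliers)
        with pytest.raises(ValueError, match="features"):
            model.score(np.zeros((3, 5)))

    def test_knn_raw_score_matches_exhaustive_search(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 3))
        k = 4
        model = ot.fit_detector(
            ot.DetectorSpec(family="knn_distance", hyperparameters={"n_neighbors": k}), X
        )
        Q = rng.normal(size=(10, 3))
        got = model.score(Q)
        # brute force: kth smallest distance to the training points
        for i, q in enumerate(Q):
            dists = np.sort(np.linalg.norm(X - q, axis=1))
            assert got[i] == pytest.approx(-dists[k - 1], abs=1e-10)


class TestNormalizeScores:
    def test_affine_map(self):
        np.testing.assert_allclose(
            ot.normalize_scores(np.array([-3.0, 0.0, 1.0])), [0, 0.75, 1]
        )

    def test_rank_preserving(self, rng):
        raw = rng.normal(size=100)
        normed = ot.normalize_scores(raw)
        assert spearmanr(raw, normed).statistic == pytest.approx(1.0)

    def test_reference_set_changes_values_not_ranking(self, rng):
        raw = rng.normal(size=50)
        ref = np.concatenate([raw, rng.normal(size=50) * 3])
        a = ot.normalize_scores(raw)
        b = ot.normalize_scores(raw, reference=ref)
        assert not np.allclose(a, b)
        np.testing.assert_array_equal(np.argsort(a), np.argsort(b))

    def test_constant_scores_map_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = ot.normalize_scores(np.ones(5))
        np.testing.assert_array_equal(out, np.full(5, 0.5))


class TestEnsemble:
    def test_two_model_toy_mean(self):
        table = pd.DataFrame({"m1": [0.2], "m2": [0.8]})
        assert ot.ensemble_average(table, ["m1", "m2"])[0] == pytest.approx(0.5)

    def test_unanimous_agreement(self):
        table = pd.DataFrame({"m1": [1.0], "m2": [1.0], "m3": [1.0]})
        assert ot.ensemble_average(table, ["m1", "m2", "m3"])[0] == 1.0

    def test_missing_column_raises(self):
        table = pd.DataFrame({"m1": [0.5]})
        with pytest.raises(KeyError):
            ot.ensemble_average(table, ["m1", "m2"])

    def test_score_table_bounds_and_mean(self, small_fixture):
        spec, molf, pairf = small_fixture
        X, is_out = build_pair_matrix(spec, molf, pairf)
        models = {
            fam: ot.fit_detector(ot.DetectorSpec(family=fam, seed=0), X[~is_out])
            for fam in ot.FAMILIES
        }
        table = ot.make_score_table(models, X, pairf.ground_truth["pair_id"])
        for fam in ot.FAMILIES:
            assert table[fam].between(0, 1).all()
        np.testing.assert_allclose(
            table["ensemble"], table[list(ot.FAMILIES)].mean(axis=1)
        )
        assert table["ensemble"].between(0, 1).all()

    def test_ensemble_auc_at_least_min_single(self, small_fixture):
        spec, molf, pairf = small_fixture
        X, is_out = build_pair_matrix(spec, molf, pairf)
        models = {
            fam: ot.fit_detector(ot.DetectorSpec(family=fam, seed=0), X[~is_out])
            for fam in ot.FAMILIES
        }
        table = ot.make_score_table(models, X, pairf.ground_truth["pair_id"])
        aucs = {fam: roc_auc_score(~is_out, table[fam]) for fam in ot.FAMILIES}
        ens = roc_auc_score(~is_out, table["ensemble"])
        assert ens >= min(aucs.values())


class TestSymmetrizedScore:
    def test_mean_of_orientations(self):
        def fake_score(X):
            # score depends on which half is first
            return np.where(X[:, 0] > X[:, 2], 0.8, 0.6)

        v = np.array([2.0, 0.0, 1.0, 0.0])
        assert ot.symmetrized_pair_score(fake_score, v) == pytest.approx(0.7)

    def test_symmetric_model_unchanged(self, blob):
        inliers, _ = blob
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 4))
        model = ot.fit_detector(ot.DetectorSpec(family="knn_distance"), X)
        v = X[7]
        sym = ot.symmetrized_pair_score(model.score, v)
        v_ba = np.concatenate([v[2:], v[:2]])
        assert sym == pytest.approx(
            (model.score(v[None])[0] + model.score(v_ba[None])[0]) / 2
        )

    def test_exact_order_invariance(self, rng):
        X = rng.normal(size=(60, 6))
        model = ot.fit_detector(ot.DetectorSpec(family="knn_distance"), X)
        for v in rng.normal(size=(100, 6)):
            v_ba = np.concatenate([v[3:], v[:3]])
            assert ot.symmetrized_pair_score(model.score, v) == ot.symmetrized_pair_score(
                model.score, v_ba
            )


class TestCrossvalTPR:
    def _bidirectional(self, rng, n_pairs=100, d=3):
        half = rng.normal(size=(n_pairs, 2 * d))
        swapped = np.hstack([half[:, d:], half[:, :d]])
        X = np.vstack([half, swapped])
        groups = np.concatenate([np.arange(n_pairs), np.arange(n_pairs)]).astype(str)
        return X, groups

    def test_folds_never_split_orientations(self, rng):
        # asserted inside crossval_tpr; this exercises the guard
        X, groups = self._bidirectional(rng)
        tprs, mean, sd = ot.crossval_tpr(
            ot.DetectorSpec(family="knn_distance"), X, groups, k=5
        )
        assert len(tprs) == 5 and 0 <= mean <= 1

    def test_accept_everything_gives_tpr_one(self, rng):
        X, groups = self._bidirectional(rng)
        # contamination quantile of identical scores accepts everything
        Xc = np.ones_like(X)
        tprs, mean, _ = ot.crossval_tpr(
            ot.DetectorSpec(family="knn_distance"), Xc, groups, k=5
        )
        assert mean == 1.0

    def test_mean_tpr_close_to_one_minus_contamination(self):
        # quantile-threshold property on i.i.d. inlier data
        means = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(1000, 4))
            groups = np.arange(1000).astype(str)
            _, mean, _ = ot.crossval_tpr(
                ot.DetectorSpec(family="knn_distance", contamination=0.05), X, groups, k=5
            )
            means.append(mean)
        assert np.mean(means) == pytest.approx(0.95, abs=0.02)

    def test_invalid_k_rejected(self, rng):
        X, groups = self._bidirectional(rng, n_pairs=10)
        with pytest.raises(ValueError):
            ot.crossval_tpr(ot.DetectorSpec(family="knn_distance"), X, groups, k=1)
        with pytest.raises(ValueError):
            ot.crossval_tpr(ot.DetectorSpec(family="knn_distance"), X, groups, k=11)


class TestTuneHyperparameters:
    def test_budget_one_returns_single_evaluated_spec(self, rng):
        X = rng.normal(size=(40, 4))
        groups = np.arange(40).astype(str)
        best, result = ot.tune_hyperparameters(
            ot.DetectorSpec(family="knn_distance"), X, groups, budget=1, seed=0, k=2
        )
        assert len(result.history) == 1
        assert best.hyperparameters == result.history[0][0]

    def test_constant_objective_seed_deterministic(self, rng):
        X = rng.normal(size=(30, 3))
        groups = np.arange(30).astype(str)
        runs = [
            ot.tune_hyperparameters(
                ot.DetectorSpec(family="knn_distance"), X, groups, budget=5,
                seed=99, objective=lambda spec: 0.5,
            )[0]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_controlled_landscape_recovers_planted_optimum(self, rng):
        X = rng.normal(size=(30, 3))
        groups = np.arange(30).astype(str)

        def objective(spec):
            k = spec.hyperparameters["n_neighbors"]
            return float(np.exp(-((k - 5) ** 2) / 8.0))

        best, _ = ot.tune_hyperparameters(
            ot.DetectorSpec(family="knn_distance"), X, groups, budget=50,
            seed=3, objective=objective,
        )
        assert best.hyperparameters["n_neighbors"] in {4, 5, 6}

    def test_returns_best_of_history(self, rng):
        X = rng.normal(size=(30, 3))
        groups = np.arange(30).astype(str)
        _, result = ot.tune_hyperparameters(
            ot.DetectorSpec(family="knn_distance"), X, groups, budget=8, seed=1, k=2
        )
        assert result.best_value == max(v for _, v in result.history)
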