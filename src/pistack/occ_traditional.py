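"""Eight traditional one-class detectors under a single scoring contract.

Every family exposes oriented raw scores with "higher = more inlier" (native
anomaly-high scores are multiplied by -1) and a decision threshold set at the
contamination-quantile of its own training scores, so that a fraction
(1 - contamination) of the training points are flagged inliers regardless of
the family's native scoring function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cluster import KMeans
from sklearn.ensemble import IsolationForest
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import GroupKFold
from sklearn.neighbors import LocalOutlierFactor, NearestNeighbors
from sklearn.svm import OneClassSVM

from . import tuning

FAMILIES = (
    "gaussian_mixture_density",
    "local_outlier_factor",
    "knn_distance",
    "isolation_forest",
    "one_class_svm",
    "histogram_density",
    "cluster_based_lof",
    "feature_bagged_lof",
)

#: default hyperparameter search spaces per family (standard ranges; the
#: originally tuned ranges are not public, so these are config-overridable).
DEFAULT_SEARCH_SPACES: dict[str, tuning.Space] = {
    "gaussian_mixture_density": {
        "n_components": ("int", 1, 8),
        "covariance_type": ("choice", ["full", "diag", "spherical"]),
    },
    "local_outlier_factor": {"n_neighbors": ("int", 2, 50)},
    "knn_distance": {"n_neighbors": ("int", 1, 50)},
    "isolation_forest": {
        "n_estimators": ("int", 50, 300),
        "max_samples": ("float", 0.3, 1.0),
    },
    "one_class_svm": {
        "gamma": ("logfloat", 1e-3, 10.0),
        "nu": ("float", 0.01, 0.5),
    },
    "histogram_density": {"n_bins": ("int", 5, 50)},
    "cluster_based_lof": {"n_clusters": ("int", 2, 12)},
    "feature_bagged_lof": {
        "n_bags": ("int", 3, 10),
        "n_neighbors": ("int", 2, 50),
        "subset_fraction": ("float", 0.5, 1.0),
    },
}


@dataclass(frozen=True)
class DetectorSpec:
    """Family + hyperparameters + contamination + seed of one detector."""

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    contamination: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown detector family {self.family!r}; choose from {FAMILIES}")
        if not 0.0 < self.contamination < 0.5:
            raise ValueError("contamination must be in (0, 0.5)")


class _HBOS:
    """Histogram-based density score: sum over features of log bin density."""

    def __init__(self, n_bins: int = 10):
        self.n_bins = n_bins

    def fit(self, X: np.ndarray) -> "_HBOS":
        self.edges_, self.logdens_ = [], []
        n = X.shape[0]
        for j in range(X.shape[1]):
            counts, edges = np.histogram(X[:, j], bins=self.n_bins)
            widths = np.diff(edges)
            dens = counts / np.maximum(n * widths, 1e-12)
            floor = 1.0 / (n * max(edges[-1] - edges[0], 1e-12) * self.n_bins)
            self.edges_.append(edges)
            self.logdens_.append(np.log(np.maximum(dens, floor * 1e-3)))
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros(X.shape[0])
        for j in range(X.shape[1]):
            edges, logdens = self.edges_[j], self.logdens_[j]
            idx = np.clip(np.searchsorted(edges, X[:, j], side="right") - 1, 0, len(logdens))
            inside = (X[:, j] >= edges[0]) & (X[:, j] <= edges[-1])
            vals = np.where(
                inside, logdens[np.clip(idx, 0, len(logdens) - 1)], logdens.min() - 5.0
            )
            out += vals
        return out


class _CBLOF:
    """Cluster-based outlier score: distance to the nearest large-cluster centroid."""

    def __init__(self, n_clusters: int = 8, alpha: float = 0.9, seed: int = 0):
        self.n_clusters = n_clusters
        self.alpha = alpha
        self.seed = seed

    def fit(self, X: np.ndarray) -> "_CBLOF":
        k = min(self.n_clusters, len(np.unique(X, axis=0)))
        km = KMeans(n_clusters=max(k, 1), n_init=4, random_state=self.seed)
        labels = km.fit_predict(X)
        sizes = np.bincount(labels, minlength=km.n_clusters)
        order = np.argsort(-sizes)
        cum = np.cumsum(sizes[order])
        boundary = int(np.searchsorted(cum, self.alpha * len(X))) + 1
        large = order[:boundary]
        self.centroids_ = km.cluster_centers_[large]
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(X[:, None, :] - self.centroids_[None, :, :], axis=2)
        return -d.min(axis=1)  # oriented: higher = more inlier


class _FeatureBaggedLOF:
    """Average of LOF scores over random feature subspaces (LOF as the base)."""

    def __init__(self, n_bags: int = 5, n_neighbors: int = 20,
                 subset_fraction: float = 1.0, seed: int = 0):
        self.n_bags = n_bags
        self.n_neighbors = n_neighbors
        self.subset_fraction = subset_fraction
        self.seed = seed

    def fit(self, X: np.ndarray) -> "_FeatureBaggedLOF":
        rng = np.random.default_rng(self.seed)
        d = X.shape[1]
        lo = max(1, d // 2)
        hi = max(lo, int(round(d * self.subset_fraction)))
        self.bags_ = []
        for _ in range(self.n_bags):
            size = int(rng.integers(lo, hi + 1))
            idx = np.sort(rng.choice(d, size=size, replace=False))
            lof = LocalOutlierFactor(
                n_neighbors=min(self.n_neighbors, X.shape[0] - 1), novelty=True
            )
            lof.fit(X[:, idx])
            self.bags_.append((idx, lof))
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return np.mean([lof.score_samples(X[:, idx]) for idx, lof in self.bags_], axis=0)


def _make_estimator(spec: DetectorSpec, n_train: int):
    hp = dict(spec.hyperparameters)
    fam = spec.family
    if fam == "gaussian_mixture_density":
        return GaussianMixture(
            n_components=min(int(hp.get("n_components", 3)), n_train),
            covariance_type=hp.get("covariance_type", "full"),
            reg_covar=float(hp.get("reg_covar", 1e-5)),
            random_state=spec.seed,
        )
    if fam == "local_outlier_factor":
        return LocalOutlierFactor(
            n_neighbors=min(int(hp.get("n_neighbors", 20)), max(n_train - 1, 1)),
            novelty=True,
        )
    if fam == "isolation_forest":
        ms = hp.get("max_samples", "auto")
        return IsolationForest(
            n_estimators=int(hp.get("n_estimators", 100)),
            max_samples=ms,
            random_state=spec.seed,
        )
    if fam == "one_class_svm":
        return OneClassSVM(
            kernel=hp.get("kernel", "rbf"),
            gamma=hp.get("gamma", "scale"),
            nu=float(hp.get("nu", 0.5)),
        )
    if fam == "histogram_density":
        return _HBOS(n_bins=int(hp.get("n_bins", 10)))
    if fam == "cluster_based_lof":
        return _CBLOF(
            n_clusters=int(hp.get("n_clusters", 8)),
            alpha=float(hp.get("alpha", 0.9)),
            seed=spec.seed,
        )
    if fam == "feature_bagged_lof":
        return _FeatureBaggedLOF(
            n_bags=int(hp.get("n_bags", 5)),
            n_neighbors=int(hp.get("n_neighbors", 20)),
            subset_fraction=float(hp.get("subset_fraction", 1.0)),
            seed=spec.seed,
        )
    raise AssertionError(fam)


@dataclass
class DetectorModel:
    """A fitted one-class scorer with oriented scores and a training threshold."""

    spec: DetectorSpec
    threshold: float = float("nan")
    _scorer: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)
    n_features_: int = 0

    def score(self, X: np.ndarray) -> np.ndarray:
        """Oriented raw scores: higher = more inlier, deterministic per model."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got shape {X.shape}"
            )
        return np.asarray(self._scorer(X), dtype=float)

    def is_inlier(self, X: np.ndarray) -> np.ndarray:
        return self.score(X) >= self.threshold


def fit_detector(spec: DetectorSpec, X_train: np.ndarray) -> DetectorModel:
    """Fit one detector and set its threshold from the training-score quantile.

    The threshold is ``np.quantile(train_scores, contamination,
    method="higher")`` and the inlier rule is ``score >= threshold``: with
    distinct scores exactly a (1 - contamination) fraction of training rows is
    flagged inlier; with massive ties (e.g. all-identical rows under the kNN
    family) everything scores at the threshold and all rows are inliers.
    """
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X_train must be a non-empty 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("X_train contains non-finite values")
    fam = spec.family
    if fam in ("gaussian_mixture_density", "local_outlier_factor") and (
        len(np.unique(X, axis=0)) == 1
    ):
        raise ValueError(f"degenerate input (single unique row) for family {fam!r}")
    if fam == "knn_distance":
        k = min(int(spec.hyperparameters.get("n_neighbors", 5)), X.shape[0])
        nn = NearestNeighbors(n_neighbors=k).fit(X)

        def scorer(Q: np.ndarray) -> np.ndarray:
            # raw score = -(distance to the kth nearest training point);
            # a training-set query counts itself as its own 0-distance neighbour
            dist, _ = nn.kneighbors(Q)
            return -dist[:, -1]

    else:
        est = _make_estimator(spec, n_train=X.shape[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X)
        scorer = est.score_samples
    model = DetectorModel(spec=spec, _scorer=scorer, n_features_=X.shape[1])
    train_scores = model._scorer(X)
    model.threshold = float(
        np.quantile(train_scores, spec.contamination, method="higher")
    )
    return model


def normalize_scores(
    raw: np.ndarray, reference: np.ndarray | None = None
) -> np.ndarray:
    """Min-max map raw scores into [0,1] using a reference score set.

    The reference defaults to the scores themselves; for cross-model
    comparison the convention is the union of labelled + candidate scores per
    model.  Order-preserving; constant references map everything to 0.5 with a
    warning.
    """
    raw = np.asarray(raw, dtype=float)
    ref = raw if reference is None else np.asarray(reference, dtype=float)
    lo, hi = ref.min(), ref.max()
    if hi == lo:
        warnings.warn("constant reference scores; mapping all to 0.5", stacklevel=2)
        return np.full(raw.shape, 0.5)
    return (raw - lo) / (hi - lo)


def ensemble_average(score_table: pd.DataFrame, model_columns: Sequence[str]) -> pd.Series:
    """Arithmetic mean of the per-model normalized score columns."""
    missing = [c for c in model_columns if c not in score_table.columns]
    if missing:
        raise KeyError(f"missing model columns: {missing}")
    return score_table[list(model_columns)].mean(axis=1)


def make_score_table(
    models: Mapping[str, DetectorModel],
    X: np.ndarray,
    pair_ids: Sequence[str],
    reference_X: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score pairs with every model, normalize to [0,1], add ensemble + flags.

    ``reference_X`` is the normalization reference set (by convention the
    union of labelled and candidate pair vectors); defaults to ``X``.
    """
    X = np.asarray(X, dtype=float)
    table = pd.DataFrame({"pair_id": list(pair_ids)})
    for name, model in models.items():
        raw = model.score(X)
        ref = raw if reference_X is None else model.score(reference_X)
        table[name] = normalize_scores(raw, ref)
        table[f"inlier_{name}"] = model.is_inlier(X)
    table["ensemble"] = ensemble_average(table, list(models))
    return table


def symmetrized_pair_score(
    score_fn: Callable[[np.ndarray], np.ndarray], vector_ab: np.ndarray
) -> float:
    """Mean of the scores of the two orientations of one pair vector.

    Guarantees exact order invariance of reported scores regardless of the
    underlying model's symmetry.
    """
    v = np.asarray(vector_ab, dtype=float)
    if v.ndim != 1 or v.shape[0] % 2 != 0:
        raise ValueError("pair vector must be 1-D with even length")
    k = v.shape[0] // 2
    v_ba = np.concatenate([v[k:], v[:k]])
    both = np.stack([v, v_ba])
    s = np.asarray(score_fn(both), dtype=float)
    return float((s[0] + s[1]) / 2.0)


def crossval_tpr(
    spec: DetectorSpec,
    X: np.ndarray,
    groups: Sequence[str],
    k: int = 5,
) -> tuple[np.ndarray, float, float]:
    """k-fold cross-validated true-positive rate on the labelled pairs.

    Folds are grouped by pair id so that both orientations of a pair land in
    the same fold (leakage guard).  Per fold: fit on the remainder, count
    validation rows scoring at or above the training threshold; TPR =
    inliers / validation-fold size.  Returns (per-fold TPRs, mean, sd).
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n_groups = len(np.unique(groups))
    if k < 2 or k > n_groups:
        raise ValueError(f"k must be in [2, {n_groups}], got {k}")
    tprs = []
    for train_idx, val_idx in GroupKFold(n_splits=k).split(X, groups=groups):
        assert not set(groups[train_idx]) & set(groups[val_idx])
        model = fit_detector(spec, X[train_idx])
        inliers = int(np.sum(model.is_inlier(X[val_idx])))
        tprs.append(inliers / len(val_idx))
    tprs = np.asarray(tprs)
    return tprs, float(tprs.mean()), float(tprs.std())


def tune_hyperparameters(
    spec_template: DetectorSpec,
    X: np.ndarray,
    groups: Sequence[str],
    budget: int,
    seed: int = 0,
    space: tuning.Space | None = None,
    k: int = 5,
    objective: Callable[[DetectorSpec], float] | None = None,
) -> tuple[DetectorSpec, tuning.TuneResult]:
    """Sequential model-based search for the spec maximizing mean CV TPR.

    ``objective`` overrides the default (mean k-fold CV TPR) -- used by tests
    with controlled landscapes.  Returns the best spec and the full history.
    """
    if space is None:
        space = DEFAULT_SEARCH_SPACES[spec_template.family]

    def default_objective(spec: DetectorSpec) -> float:
        _, mean_tpr, _ = crossval_tpr(spec, X, groups, k=k)
        return mean_tpr

    obj = objective or default_objective

    def wrapped(params: dict) -> float:
        spec = DetectorSpec(
            family=spec_template.family,
            hyperparameters={**dict(spec_template.hyperparameters), **params},
            contamination=spec_template.contamination,
            seed=spec_template.seed,
        )
        return obj(spec)

    result = tuning.maximize(wrapped, space, budget=budget, seed=seed)
    best = DetectorSpec(
        family=spec_template.family,
        hyperparameters={**dict(spec_template.hyperparameters), **result.best_params},
        contamination=spec_template.contamination,
        seed=spec_template.seed,
    )
    return best, result
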