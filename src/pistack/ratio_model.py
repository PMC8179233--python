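"""Stoichiometry prediction: 1:1 (label 0) vs higher ratios (label 1).

The classifier is a gradient-boosted decision-tree model trained on deep
latent representations (a config switch allows raw pair features for
ablation).  Class imbalance is handled by minority oversampling through
convex interpolation between nearest minority neighbours, applied to the
training split only -- never to the held-out test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from . import tuning
from .data_model import PairRecord

RATIO_SEARCH_SPACE: tuning.Space = {
    "n_estimators": ("int", 50, 300),
    "learning_rate": ("logfloat", 0.01, 0.5),
    "max_depth": ("int", 2, 6),
}


def label_ratio(pair: PairRecord) -> int:
    """0 iff the stoichiometric counts are exactly {1, 1}; 1 otherwise.

    The rule is applied literally: any count multiset other than {1,1}
    (including symmetric ones like {2,2}) maps to label 1.
    """
    if pair.counts is None or set(pair.counts) != {pair.mol_a, pair.mol_b}:
        raise ValueError(f"pair {pair.pair_id} is missing stoichiometric counts")
    counts = sorted(int(v) for v in pair.counts.values())
    return 0 if counts == [1, 1] else 1


def balance_classes(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample the minority class by convex interpolation (SMOTE).

    Each synthetic point is ``x1 + u * (x2 - x1)`` with ``x2`` one of the k
    nearest minority neighbours of a random minority point ``x1`` and
    ``u ~ U(0,1)``, so every synthetic point lies on a segment between two
    original minority points.  Returns ``(X_bal, y_bal, synthetic_mask)``;
    already-balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balancing needs both classes present")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X, y, np.zeros(len(y), dtype=bool)
    X_min = X[y == minority]
    if X_min.shape[0] < 2:
        raise ValueError("minority class needs >= 2 points for interpolation")
    rng = np.random.default_rng(seed)
    k = min(k_neighbors, X_min.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, nbrs = nn.kneighbors(X_min)  # column 0 is the point itself
    synth = np.empty((n_needed, X.shape[1]))
    for i in range(n_needed):
        a = int(rng.integers(X_min.shape[0]))
        b = int(nbrs[a, 1 + rng.integers(k)])
        u = float(rng.uniform())
        synth[i] = X_min[a] + u * (X_min[b] - X_min[a])
    X_bal = np.vstack([X, synth])
    y_bal = np.concatenate([y, np.full(n_needed, minority)])
    mask = np.concatenate([np.zeros(len(y), dtype=bool), np.ones(n_needed, dtype=bool)])
    return X_bal, y_bal, mask


@dataclass
class RatioReport:
    train_accuracy: float
    test_accuracy: float
    n_train: int
    n_test: int
    class_counts_before: dict
    class_counts_after: dict
    best_params: dict


def train_ratio_classifier(
    X: np.ndarray,
    y: np.ndarray,
    budget: int = 1,
    seed: int = 0,
    test_size: float = 0.25,
) -> tuple[GradientBoostingClassifier, RatioReport]:
    """Split, balance the training side only, tune and fit the GBDT classifier.

    The train/test split is made *before* balancing so the test accuracy is
    computed on untouched data.  ``budget=1`` skips the search and uses the
    default hyperparameters.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValueError("degenerate split: a side is missing a class")
    before = {int(c): int(n) for c, n in zip(*np.unique(y_tr, return_counts=True))}
    X_bal, y_bal, _ = balance_classes(X_tr, y_tr, seed=seed)
    after = {int(c): int(n) for c, n in zip(*np.unique(y_bal, return_counts=True))}

    def make_clf(params: dict) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            n_estimators=int(params.get("n_estimators", 100)),
            learning_rate=float(params.get("learning_rate", 0.1)),
            max_depth=int(params.get("max_depth", 3)),
            random_state=seed,
        )

    best_params: dict = {}
    if budget > 1:
        def objective(params: dict) -> float:
            skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
            accs = []
            for tr, va in skf.split(X_bal, y_bal):
                clf = make_clf(params).fit(X_bal[tr], y_bal[tr])
                accs.append(clf.score(X_bal[va], y_bal[va]))
            return float(np.mean(accs))

        result = tuning.maximize(objective, RATIO_SEARCH_SPACE, budget=budget, seed=seed)
        best_params = result.best_params
    clf = make_clf(best_params).fit(X_bal, y_bal)
    report = RatioReport(
        train_accuracy=float(clf.score(X_tr, y_tr)),
        test_accuracy=float(clf.score(X_te, y_te)),
        n_train=len(y_tr),
        n_test=len(y_te),
        class_counts_before=before,
        class_counts_after=after,
        best_params=best_params,
    )
    return clf, report


def predict_ratio_class(
    classifier: GradientBoostingClassifier, latents: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class probabilities for candidate latent vectors."""
    latents = np.asarray(latents, dtype=float)
    proba = classifier.predict_proba(latents)
    labels = classifier.classes_[np.argmax(proba, axis=1)]
    return labels.astype(int), proba
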