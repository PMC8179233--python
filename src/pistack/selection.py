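"""Candidate selection: thresholding, popularity, Pareto front, neighbours, 2D QC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import pearsonr


@dataclass
class SelectionConfig:
    """Thresholds and constraint flags for building the final candidate report."""

    inlier_threshold: float = 0.7
    quartile_fraction: float = 0.25
    reference_smiles: str | None = None  # similarity objective reference
    exclude_one_ring: bool = False
    exclude_heteroatoms: bool = False
    restrict_to_coformer: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.inlier_threshold <= 1.0:
            raise ValueError("inlier_threshold must be in [0,1]")


def flag_inliers(
    score_table: pd.DataFrame, threshold: float = 0.7, score_col: str = "score"
) -> pd.DataFrame:
    """Pairs with score strictly greater than the threshold."""
    scores = score_table[score_col]
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError("scores must be normalized to [0,1]")
    return score_table[scores > threshold]


def top_quartile(
    score_table: pd.DataFrame, fraction: float = 0.25, score_col: str = "score"
) -> pd.DataFrame:
    """The floor(n * fraction) highest-scoring pairs, ties broken by pair_id."""
    n = len(score_table)
    m = int(np.floor(n * fraction))
    if n == 0 or m == 0:
        return score_table.iloc[:0]
    ordered = score_table.sort_values(
        [score_col, "pair_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered.head(m)


def coformer_popularity(pairs: pd.DataFrame) -> pd.Series:
    """Appearance count per molecule over a pair subset, ranked descending.

    Each pair contributes 1 to each of its two molecules, so the counts
    satisfy the handshake identity sum(counts) == 2 * n_pairs.
    """
    if len(pairs) == 0:
        return pd.Series(dtype=int, name="count")
    ids = pd.concat([pairs["mol_a"], pairs["mol_b"]])
    counts = ids.value_counts()
    # deterministic tie-break by molecule id
    order = sorted(counts.index, key=lambda m: (-counts[m], m))
    return counts.loc[order].rename("count")


@dataclass
class ParetoResult:
    """Per-candidate objectives with the non-dominated front marked."""

    table: pd.DataFrame  # columns: objective columns + on_front
    front_ids: list = field(default_factory=list)


def pareto_front(
    candidates: pd.DataFrame, objectives: tuple[str, str] = ("score", "similarity")
) -> ParetoResult:
    """Mark the non-dominated candidates under two maximization objectives.

    x dominates y iff x >= y in both objectives and x > y in at least one;
    exact ties are kept on the front.  O(n log n) sweep over the candidates
    sorted by the first objective.
    """
    obj1, obj2 = objectives
    vals = candidates[[obj1, obj2]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("objectives must be finite")
    n = len(candidates)
    on_front = np.zeros(n, dtype=bool)
    order = np.argsort(-vals[:, 0], kind="mergesort")
    best2_prev = -np.inf  # max obj2 among strictly larger obj1
    i = 0
    while i < n:
        j = i
        group_max2 = -np.inf
        while j < n and vals[order[j], 0] == vals[order[i], 0]:
            group_max2 = max(group_max2, vals[order[j], 1])
            j += 1
        for t in range(i, j):
            idx = order[t]
            if vals[idx, 1] == group_max2 and vals[idx, 1] > best2_prev:
                on_front[idx] = True
        best2_prev = max(best2_prev, group_max2)
        i = j
    table = candidates.copy()
    table["on_front"] = on_front
    front_ids = list(table.index[on_front])
    return ParetoResult(table=table, front_ids=front_ids)


def nearest_known_pairs(
    query_vector: np.ndarray,
    labelled_vectors: np.ndarray,
    pair_ids: list[str],
    k: int,
) -> pd.DataFrame:
    """The k labelled pairs nearest to the query by Euclidean distance.

    ``labelled_vectors`` has shape (n_pairs, 2, d) or (n_pairs, 2d); the
    distance per labelled pair is the minimum over its two orientations
    (query kept in its canonical orientation), so the result does not depend
    on how either pair was oriented.  Ties are broken by pair_id; if k
    exceeds the dataset a warning is raised and everything is returned.
    """
    q = np.asarray(query_vector, dtype=float).ravel()
    L = np.asarray(labelled_vectors, dtype=float)
    if L.ndim == 2:
        if L.shape[1] != q.shape[0]:
            raise ValueError("dimensionality mismatch between query and labelled vectors")
        half = q.shape[0] // 2
        L = L.reshape(L.shape[0], 2, half)
    d = L.shape[2]
    if q.shape[0] != 2 * d:
        raise ValueError("dimensionality mismatch between query and labelled vectors")
    flat_ab = L.reshape(L.shape[0], 2 * d)
    flat_ba = L[:, ::-1, :].reshape(L.shape[0], 2 * d)
    dist = np.minimum(
        cdist(q[None, :], flat_ab)[0], cdist(q[None, :], flat_ba)[0]
    )
    df = pd.DataFrame({"pair_id": pair_ids, "distance": dist})
    df = df.sort_values(["distance", "pair_id"], kind="mergesort").reset_index(drop=True)
    if k > len(df):
        warnings.warn(
            f"k={k} exceeds dataset size {len(df)}; returning all pairs", stacklevel=2
        )
        return df
    return df.head(k)


def distance_preservation_score(X_high: np.ndarray, X_low: np.ndarray) -> float:
    """Pearson correlation between condensed pairwise distances in the two spaces."""
    X_high = np.asarray(X_high, dtype=float)
    X_low = np.asarray(X_low, dtype=float)
    if X_high.shape[0] != X_low.shape[0]:
        raise ValueError("both embeddings must have the same number of points")
    if X_high.shape[0] < 3:
        raise ValueError("need at least 3 points for the QC correlation")
    return float(pearsonr(pdist(X_high), pdist(X_low)).statistic)


def embed_2d_qc(
    X: np.ndarray,
    n_neighbors: int = 80,
    min_dist: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """UMAP 2D projection plus its distance-preservation QC score.

    The manifold projection itself is an external component; the defined
    computation here is the QC metric: Pearson correlation between the
    condensed pairwise-distance matrices in full dimension and in 2D.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1 = {n_neighbors + 1} points, got {X.shape[0]}"
        )
    import umap  # deferred: numba compilation is expensive

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric="euclidean",
            n_components=2,
            random_state=seed,
        )
        coords = reducer.fit_transform(X)
    return coords, distance_preservation_score(X, coords)
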