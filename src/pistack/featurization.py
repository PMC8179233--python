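"""Descriptor engineering: pruning, complementarity selection, scaling, pair vectors.

The feature-selection step keeps descriptors whose values are *pairwise
correlated between the two co-formers* across known pairs (molecular
complementarity): a descriptor survives iff both Pearson and Spearman
correlations between co-former A's and co-former B's values exceed the
threshold and both p-values are significant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PairRecord


@dataclass
class FeatureSelectionResult:
    """Outcome of the complementarity-driven feature selection."""

    kept_indices: list[int]
    pearson_r: np.ndarray
    spearman_r: np.ndarray
    pearson_p: np.ndarray
    spearman_p: np.ndarray
    corr_min: float
    p_max: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "kept_indices": [int(i) for i in self.kept_indices],
                "pearson_r": self.pearson_r.tolist(),
                "spearman_r": self.spearman_r.tolist(),
                "pearson_p": self.pearson_p.tolist(),
                "spearman_p": self.spearman_p.tolist(),
                "corr_min": self.corr_min,
                "p_max": self.p_max,
            }
        )


@dataclass
class ScalerModel:
    """Per-feature min-max scaler fitted on the labelled molecules only.

    Transforming the fitting set maps every feature into [0,1]; candidate-set
    values may fall outside that range (no clipping), which is intentional:
    the same molecule must receive the identical scaled vector in every pair
    it participates in.
    """

    mins: np.ndarray
    maxs: np.ndarray
    _range: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValueError("scaler maxs must be >= mins")
        self._range = self.maxs - self.mins

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros_like(X)
        nz = self._range > 0
        out[..., nz] = (X[..., nz] - self.mins[nz]) / self._range[nz]
        return out

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self._range + self.mins

    def to_json(self) -> str:
        return json.dumps({"mins": self.mins.tolist(), "maxs": self.maxs.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ScalerModel":
        d = json.loads(text)
        return cls(mins=np.asarray(d["mins"]), maxs=np.asarray(d["maxs"]))


@dataclass(frozen=True)
class PairFeatureVector:
    """Concatenation of the two scaled per-molecule vectors for one pair."""

    pair_id: str
    vector: np.ndarray
    orientation: str  # {"ab", "ba"}


def prune_descriptors(
    matrix: np.ndarray, corr_max: float = 0.92, var_min: float = 0.4
) -> list[int]:
    """Remove low-variance and mutually redundant descriptor columns.

    Columns with population variance (ddof=0) below ``var_min`` are removed
    first; then a greedy scan in column order drops the *later* column of any
    pair with ``|r| > corr_max`` (absolute correlation; deterministic
    tie-break by column order).

    Returns the surviving column indices, sorted ascending.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("matrix must be 2-D with at least one column")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains missing/non-finite values; drop them first")
    var = X.var(axis=0)
    candidates = [j for j in range(X.shape[1]) if var[j] >= var_min]
    if not candidates:
        warnings.warn("all descriptor columns removed by the variance filter", stacklevel=2)
        return []
    sub = X[:, candidates]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.atleast_2d(corr)
    kept: list[int] = []
    for local_j, j in enumerate(candidates):
        redundant = any(
            abs(corr[local_i, local_j]) > corr_max
            for local_i, i in enumerate(candidates)
            if i in kept and np.isfinite(corr[local_i, local_j])
        )
        if not redundant:
            kept.append(j)
    return kept


def select_complementary_features(
    a_values: np.ndarray,
    b_values: np.ndarray,
    corr_min: float = 0.4,
    p_max: float = 1e-3,
) -> FeatureSelectionResult:
    """Keep descriptors correlated between the two co-formers across pairs.

    Parameters
    ----------
    a_values, b_values
        Arrays of shape (n_pairs, n_features): descriptor values of co-former A
        and co-former B for each labelled pair (solvent-containing pairs
        already removed).  Both orientations contribute symmetrically: the
        correlation for feature j is computed on the stacked samples
        ``([a_j; b_j], [b_j; a_j])``, so the result is invariant under a
        global A/B swap.  Note the stacking doubles n and therefore shrinks
        p-values; this is the documented convention.
    corr_min, p_max
        A feature is kept iff Pearson r > corr_min AND Spearman r > corr_min
        AND both p-values < p_max.
    """
    A = np.asarray(a_values, dtype=float)
    B = np.asarray(b_values, dtype=float)
    if A.shape != B.shape:
        raise ValueError("a_values and b_values must have identical shape")
    n_pairs, n_feat = A.shape
    if n_pairs < 3:
        raise ValueError(
            f"need at least 3 labelled pairs for correlation p-values, got {n_pairs}"
        )
    pr = np.full(n_feat, np.nan)
    sr = np.full(n_feat, np.nan)
    pp = np.ones(n_feat)
    sp = np.ones(n_feat)
    for j in range(n_feat):
        x = np.concatenate([A[:, j], B[:, j]])
        y = np.concatenate([B[:, j], A[:, j]])
        if np.std(x) == 0 or np.std(y) == 0:
            pr[j] = sr[j] = 0.0
            continue
        pres = stats.pearsonr(x, y)
        sres = stats.spearmanr(x, y)
        pr[j], pp[j] = pres.statistic, pres.pvalue
        sr[j], sp[j] = sres.statistic, sres.pvalue
    kept = [
        j
        for j in range(n_feat)
        if pr[j] > corr_min and sr[j] > corr_min and pp[j] < p_max and sp[j] < p_max
    ]
    return FeatureSelectionResult(
        kept_indices=kept,
        pearson_r=pr,
        spearman_r=sr,
        pearson_p=pp,
        spearman_p=sp,
        corr_min=corr_min,
        p_max=p_max,
    )


def fit_scaler(labelled_features: np.ndarray) -> ScalerModel:
    """Fit the min-max scaler on the labelled (co-crystal-forming) molecules."""
    X = np.asarray(labelled_features, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("fitting set must be a non-empty 2-D array")
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    if np.any(maxs == mins):
        n = int(np.sum(maxs == mins))
        warnings.warn(
            f"{n} zero-range feature(s); they will be mapped to 0", stacklevel=2
        )
    return ScalerModel(mins=mins, maxs=maxs)


def build_pair_vectors(
    pairs: Sequence[PairRecord],
    scaled_features: Mapping[str, np.ndarray] | pd.DataFrame,
    bidirectional: bool,
) -> list[PairFeatureVector]:
    """Concatenate the two scaled molecule vectors of each pair.

    With ``bidirectional=True`` (training) both orientations are emitted per
    pair -- the input representation must be invariant to the position of the
    molecule in the vector.  With ``bidirectional=False`` one canonical
    orientation (sorted mol_id) is emitted per pair.  The ``pair_id`` is
    identical across the two orientations of a pair.
    """
    feats = _as_feature_lookup(scaled_features)
    out: list[PairFeatureVector] = []
    for pair in pairs:
        if pair.mol_a == pair.mol_b:
            raise ValueError(f"self-pair not allowed: {pair.mol_a}")
        for mid in (pair.mol_a, pair.mol_b):
            if mid not in feats:
                raise KeyError(f"no features for molecule {mid!r} (pair {pair.pair_id})")
        va = np.asarray(feats[pair.mol_a], dtype=float)
        vb = np.asarray(feats[pair.mol_b], dtype=float)
        out.append(
            PairFeatureVector(pair.pair_id, np.concatenate([va, vb]), orientation="ab")
        )
        if bidirectional:
            out.append(
                PairFeatureVector(pair.pair_id, np.concatenate([vb, va]), orientation="ba")
            )
    return out


def pair_matrix(vectors: Sequence[PairFeatureVector]) -> tuple[np.ndarray, list[str]]:
    """Stack pair vectors into a matrix; returns (X, pair_ids row labels)."""
    X = np.stack([v.vector for v in vectors])
    ids = [v.pair_id for v in vectors]
    return X, ids


def _as_feature_lookup(scaled_features) -> Mapping[str, np.ndarray]:
    if isinstance(scaled_features, pd.DataFrame):
        return {str(i): row.to_numpy(dtype=float) for i, row in scaled_features.iterrows()}
    return scaled_features
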