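"""Shapley-value attribution of pair scores and descriptor correlation mapping.

Attributions are computed on the deep score *before* [0,1] normalization
(attribution of an affine transform only rescales values).  The estimator is
exact coalition enumeration for small feature counts and a seeded
permutation-sampling estimator above that, with a reported Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class AttributionTable:
    """Per-pair per-feature Shapley values plus the efficiency bookkeeping.

    ``values`` is (pairs x features); ``scores`` holds f(x) per pair and
    ``base_value`` the background expectation, so the efficiency axiom reads
    ``values.sum(axis=1) ~= scores - base_value``.
    """

    values: pd.DataFrame
    scores: pd.Series
    base_value: float
    background_description: str
    mc_error: pd.DataFrame | None = None

    @property
    def global_importance(self) -> pd.Series:
        """Mean absolute Shapley value per feature, descending."""
        return self.values.abs().mean(axis=0).sort_values(ascending=False)


def _check_deterministic(f: Callable[[np.ndarray], np.ndarray], probe: np.ndarray) -> None:
    a = np.asarray(f(probe), dtype=float)
    b = np.asarray(f(probe), dtype=float)
    if not np.array_equal(a, b):
        raise ValueError("score function is not deterministic; attribution contract requires it")


def _exact_shapley(
    f: Callable[[np.ndarray], np.ndarray], background: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exhaustive coalition enumeration; O(2^k * |background|) evaluations."""
    k = x.shape[0]
    m = background.shape[0]
    v = np.empty(1 << k)
    for mask in range(1 << k):
        sel = np.array([(mask >> j) & 1 for j in range(k)], dtype=bool)
        batch = np.where(sel[None, :], x[None, :], background)
        v[mask] = float(np.mean(f(batch)))
    fact = [factorial(i) for i in range(k + 1)]
    weights = [fact[s] * fact[k - s - 1] / fact[k] for s in range(k)]
    phi = np.zeros(k)
    for mask in range(1 << k):
        s = bin(mask).count("1")
        for j in range(k):
            if not (mask >> j) & 1:
                phi[j] += weights[s] * (v[mask | (1 << j)] - v[mask])
    return phi, float(v[0])


def _sampled_shapley(
    f: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    x: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Permutation-sampling estimator; efficiency holds by telescoping."""
    k = x.shape[0]
    contribs = np.zeros((n_permutations, k))
    base_vals = np.zeros(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(k)
        bg = background[int(rng.integers(background.shape[0]))]
        rows = np.tile(bg, (k + 1, 1))
        for step, j in enumerate(perm, start=1):
            rows[step:, j] = x[j]
        vals = np.asarray(f(rows), dtype=float)
        contribs[p, perm] = np.diff(vals)
        base_vals[p] = vals[0]
    phi = contribs.mean(axis=0)
    stderr = contribs.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return phi, float(base_vals.mean()), stderr


def shapley_attribution(
    score_function: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    pairs: np.ndarray,
    pair_ids: Sequence[str] | None = None,
    feature_names: Sequence[str] | None = None,
    max_exact: int = 12,
    n_permutations: int = 256,
    seed: int = 0,
) -> AttributionTable:
    """Additive Shapley attribution of a deterministic score function.

    Parameters
    ----------
    score_function
        Vectorized map (n, d) -> (n,) of pair vectors to raw scores.  Must be
        deterministic (checked).
    background
        Reference sample of pair vectors; the value of the empty coalition is
        the mean score over this sample.
    pairs
        Pair vectors (n_pairs, d) to explain.
    max_exact
        Use exhaustive coalition enumeration up to this many features; the
        seeded permutation-sampling estimator (with Monte-Carlo error) above.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background sample must be non-empty")
    _check_deterministic(score_function, background[: min(4, background.shape[0])])
    d = pairs.shape[1]
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(d)]
    ids = list(pair_ids) if pair_ids is not None else [f"pair{i}" for i in range(pairs.shape[0])]
    rng = np.random.default_rng(seed)
    rows, errs, bases = [], [], []
    for x in pairs:
        if d <= max_exact:
            phi, base = _exact_shapley(score_function, background, x)
            err = np.zeros(d)
        else:
            phi, base, err = _sampled_shapley(
                score_function, background, x, n_permutations, rng
            )
        rows.append(phi)
        errs.append(err)
        bases.append(base)
    values = pd.DataFrame(np.asarray(rows), index=ids, columns=names)
    scores = pd.Series(
        np.asarray(score_function(pairs), dtype=float), index=ids, name="score"
    )
    mc = None if d <= max_exact else pd.DataFrame(np.asarray(errs), index=ids, columns=names)
    return AttributionTable(
        values=values,
        scores=scores,
        base_value=float(np.mean(bases)),
        background_description=f"{background.shape[0]} reference pair vectors",
        mc_error=mc,
    )


def subset_attribution(table: AttributionTable, pair_ids: Sequence[str]) -> pd.Series:
    """Global importances recomputed over a subset of pairs only."""
    ids = [i for i in pair_ids if i in table.values.index]
    if not ids:
        raise ValueError("subset selects no pairs")
    return table.values.loc[ids].abs().mean(axis=0).sort_values(ascending=False)


def map_to_interpretable(
    global_importance: pd.Series,
    descriptor_matrix: pd.DataFrame,
    interpretable: Sequence[str],
    r_min: float = 0.75,
    top_n: int = 6,
) -> Mapping[str, list[tuple[str, float]]]:
    """Relate top-ranked important descriptors to interpretable ones by correlation.

    For each of the ``top_n`` most important descriptors, lists the
    interpretable descriptors whose absolute Pearson correlation across
    molecules exceeds ``r_min``.
    """
    if not list(interpretable):
        raise ValueError("interpretable descriptor subset must be non-empty")
    missing = [c for c in interpretable if c not in descriptor_matrix.columns]
    if missing:
        raise KeyError(f"interpretable descriptors not in matrix: {missing}")
    out: dict[str, list[tuple[str, float]]] = {}
    for name in global_importance.index[:top_n]:
        if name not in descriptor_matrix.columns:
            continue
        x = descriptor_matrix[name].to_numpy(dtype=float)
        hits = []
        for other in interpretable:
            if other == name:
                continue
            y = descriptor_matrix[other].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) > r_min:
                hits.append((other, r))
        out[name] = sorted(hits, key=lambda t: -abs(t[1]))
    return out
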