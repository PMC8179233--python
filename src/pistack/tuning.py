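"""Seeded sequential model-based hyperparameter search (TPE-style).

After a random warm-up, observations are split at a quantile into "good" and
"bad"; new proposals are drawn from a kernel density over the good
observations and ranked by the good/bad density ratio, so later proposals
concentrate near earlier high scorers.  Fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

Space = Mapping[str, tuple]
# dimension forms:
#   ("int", lo, hi)           inclusive integer range
#   ("float", lo, hi)         uniform real range
#   ("logfloat", lo, hi)      log-uniform real range
#   ("choice", [v0, v1, ...]) categorical


@dataclass
class TuneResult:
    best_params: dict
    best_value: float
    history: list[tuple[dict, float]]


def _sample_uniform(space: Space, rng: np.random.Generator) -> dict:
    params = {}
    for name, dim in space.items():
        kind = dim[0]
        if kind == "int":
            params[name] = int(rng.integers(dim[1], dim[2] + 1))
        elif kind == "float":
            params[name] = float(rng.uniform(dim[1], dim[2]))
        elif kind == "logfloat":
            params[name] = float(np.exp(rng.uniform(np.log(dim[1]), np.log(dim[2]))))
        elif kind == "choice":
            params[name] = dim[1][int(rng.integers(len(dim[1])))]
        else:
            raise ValueError(f"unknown dimension kind {kind!r}")
    return params


def _kde_logpdf(value, observed: list, dim: tuple) -> float:
    kind = dim[0]
    if kind == "choice":
        counts = np.array([sum(1 for o in observed if o == v) for v in dim[1]], dtype=float)
        probs = (counts + 1.0) / (counts.sum() + len(dim[1]))
        return float(np.log(probs[dim[1].index(value)]))
    if kind == "logfloat":
        obs = np.log(np.asarray(observed, dtype=float))
        v = np.log(value)
        width = np.log(dim[2]) - np.log(dim[1])
    else:
        obs = np.asarray(observed, dtype=float)
        v = float(value)
        width = dim[2] - dim[1]
    bw = max(width / max(len(obs), 1) ** 0.5, 1e-6 * max(width, 1.0))
    dens = np.exp(-0.5 * ((v - obs) / bw) ** 2).mean() / (bw * np.sqrt(2 * np.pi))
    return float(np.log(dens + 1e-300))


def _sample_near(good: list[dict], space: Space, rng: np.random.Generator) -> dict:
    """Perturb a random good observation (kernel sample per dimension)."""
    base = good[int(rng.integers(len(good)))]
    params = {}
    for name, dim in space.items():
        kind = dim[0]
        if kind == "choice":
            if rng.uniform() < 0.8:
                params[name] = base[name]
            else:
                params[name] = dim[1][int(rng.integers(len(dim[1])))]
            continue
        if kind == "logfloat":
            lo, hi = np.log(dim[1]), np.log(dim[2])
            center = np.log(base[name])
        else:
            lo, hi = float(dim[1]), float(dim[2])
            center = float(base[name])
        bw = (hi - lo) / max(len(good), 1) ** 0.5
        val = np.clip(center + rng.normal(0.0, max(bw, 1e-9)), lo, hi)
        if kind == "logfloat":
            params[name] = float(min(dim[2], max(dim[1], np.exp(val))))
        elif kind == "int":
            params[name] = int(round(val))
        else:
            params[name] = float(val)
    return params


def maximize(
    objective: Callable[[dict], float],
    space: Space,
    budget: int,
    seed: int = 0,
    n_warmup: int | None = None,
    gamma: float = 0.25,
    n_candidates: int = 24,
    explore: float = 0.15,
) -> TuneResult:
    """Maximize ``objective`` over ``space`` within ``budget`` evaluations.

    ``explore`` is the probability of an unconditioned uniform draw after the
    warm-up phase (guards against the proposal distribution locking onto a
    clipped boundary value in small discrete spaces).
    """
    if not space:
        raise ValueError("empty search space")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    if n_warmup is None:
        n_warmup = max(3, budget // 4)
    history: list[tuple[dict, float]] = []
    seen: set[tuple] = set()
    for it in range(budget):
        if it < n_warmup or len(history) < 3 or rng.uniform() < explore:
            params = _sample_uniform(space, rng)
        else:
            values = np.array([v for _, v in history])
            cutoff = np.quantile(values, 1.0 - gamma)
            good = [p for p, v in history if v >= cutoff] or [max(history, key=lambda h: h[1])[0]]
            bad = [p for p, v in history if v < cutoff] or good
            cands = [_sample_near(good, space, rng) for _ in range(n_candidates)]
            scores = []
            for cand in cands:
                lg = sum(
                    _kde_logpdf(cand[n], [g[n] for g in good], d) for n, d in space.items()
                )
                lb = sum(
                    _kde_logpdf(cand[n], [b[n] for b in bad], d) for n, d in space.items()
                )
                scores.append(lg - lb)
            params = cands[int(np.argmax(scores))]
        key = tuple(sorted(params.items()))
        if key in seen:  # don't re-evaluate identical points in discrete spaces
            params = _sample_uniform(space, rng)
            key = tuple(sorted(params.items()))
        seen.add(key)
        history.append((params, float(objective(params))))
    best_params, best_value = max(history, key=lambda h: h[1])
    return TuneResult(best_params=dict(best_params), best_value=best_value, history=history)
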