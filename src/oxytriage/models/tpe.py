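"""Tree-structured Parzen Estimator search over declarative spaces.

A compact TPE in the spirit of Bergstra et al.'s algorithm: past trials are
split at the gamma-quantile of the objective into "good" and "bad" sets, each
parameter gets a pair of Parzen density estimates (Gaussian mixtures for
numeric ranges, smoothed counts for categoricals), and the next point is the
candidate maximizing the good/bad density ratio.  Numeric parameters are
sampled continuously inside their declared bounds; rounding of integer-valued
engine parameters happens at the engine boundary, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = ["Trial", "tpe_search"]


@dataclass(frozen=True)
class Trial:
    params: dict
    value: float


def _is_numeric_range(spec: object) -> bool:
    return (
        isinstance(spec, tuple)
        and len(spec) == 2
        and all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in spec)
    )


def _sample_prior(spec: object, rng: np.random.Generator) -> object:
    if _is_numeric_range(spec):
        lo, hi = float(spec[0]), float(spec[1])
        return float(rng.uniform(lo, hi))
    choices = list(spec)
    return choices[int(rng.integers(len(choices)))]


def _mixture_logpdf(x: np.ndarray, obs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Parzen mixture over ``obs`` with a uniform prior component, truncated
    to [lo, hi] only through bandwidth choice (densities need not integrate
    to one - only ratios matter)."""
    span = hi - lo
    bw = max(span / max(len(obs), 1) ** 0.5, 1e-3 * span, 1e-12)
    diff = (x[:, None] - obs[None, :]) / bw
    comp = np.exp(-0.5 * diff**2) / (bw * np.sqrt(2 * np.pi))
    prior = 1.0 / span if span > 0 else 1.0
    dens = (comp.sum(axis=1) + prior) / (len(obs) + 1)
    return np.log(dens)


def _categorical_logpmf(x: Sequence, obs: Sequence, choices: Sequence) -> np.ndarray:
    counts = {c: 1.0 for c in choices}  # add-one smoothing
    for o in obs:
        counts[o] += 1.0
    total = sum(counts.values())
    return np.log(np.array([counts[v] / total for v in x]))


def tpe_search(
    search_space: Mapping[str, object],
    objective: Callable[[Mapping[str, object]], float],
    max_evals: int = 50,
    seed: int = 0,
    gamma: float = 0.25,
    n_startup: int = 10,
    n_candidates: int = 24,
) -> tuple[dict, list[Trial]]:
    """Minimize ``objective`` over ``search_space``.

    Returns the best parameter dict and the full trials log; the best trial's
    value equals the minimum over the log, and every sampled point lies
    inside the declared bounds.
    """
    if max_evals < 1:
        raise ValueError("max_evals must be >= 1")
    if not search_space:
        raise ValueError("search_space must not be empty")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for it in range(max_evals):
        if it < n_startup or len(trials) < 2:
            params = {k: _sample_prior(spec, rng) for k, spec in search_space.items()}
        else:
            params = _suggest(search_space, trials, rng, gamma, n_candidates)
        value = float(objective(params))
        trials.append(Trial(params=dict(params), value=value))
    best = min(trials, key=lambda t: t.value)
    return dict(best.params), trials


def _suggest(
    search_space: Mapping[str, object],
    trials: list[Trial],
    rng: np.random.Generator,
    gamma: float,
    n_candidates: int,
) -> dict:
    order = np.argsort([t.value for t in trials], kind="stable")
    n_good = max(1, int(np.ceil(gamma * len(trials))))
    good = [trials[i] for i in order[:n_good]]
    bad = [trials[i] for i in order[n_good:]] or good
    score = np.zeros(n_candidates)
    cand: dict[str, list] = {}
    for name, spec in search_space.items():
        g_obs = [t.params[name] for t in good]
        b_obs = [t.params[name] for t in bad]
        if _is_numeric_range(spec):
            lo, hi = float(spec[0]), float(spec[1])
            g_arr = np.asarray(g_obs, dtype=float)
            centers = g_arr[rng.integers(len(g_arr), size=n_candidates)]
            bw = max((hi - lo) / max(len(g_arr), 1) ** 0.5, 1e-3 * (hi - lo))
            draws = np.clip(centers + rng.normal(0.0, bw, size=n_candidates), lo, hi)
            score += _mixture_logpdf(draws, g_arr, lo, hi)
            score -= _mixture_logpdf(draws, np.asarray(b_obs, dtype=float), lo, hi)
            cand[name] = [float(v) for v in draws]
        else:
            choices = list(spec)
            counts = {c: 1.0 for c in choices}
            for o in g_obs:
                counts[o] += 1.0
            probs = np.array([counts[c] for c in choices])
            probs = probs / probs.sum()
            idx = rng.choice(len(choices), size=n_candidates, p=probs)
            draws = [choices[i] for i in idx]
            score += _categorical_logpmf(draws, g_obs, choices)
            score -= _categorical_logpmf(draws, b_obs, choices)
            cand[name] = draws
    best = int(np.argmax(score))
    return {name: values[best] for name, values in cand.items()}
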