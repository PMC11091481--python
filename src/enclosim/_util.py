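"""Small numeric helpers used across modules."""
from __future__ import annotations

import numpy as np


def largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Round ``fractions * total`` to integers summing exactly to ``total``.

    Deterministic: remainder ties are broken by ascending index.
    """
    fractions = np.asarray(fractions, dtype=float)
    if total < 0:
        raise ValueError("total must be non-negative")
    s = fractions.sum()
    if s <= 0:
        raise ValueError("fractions must have positive sum")
    quota = fractions / s * total
    base = np.floor(quota).astype(int)
    short = total - int(base.sum())
    if short > 0:
        # stable argsort => ties broken by index
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def weighted_quantile(values: np.ndarray, q, weights: np.ndarray) -> np.ndarray:
    """Weighted empirical quantiles (inverse-CDF on the weighted sample)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return np.interp(np.atleast_1d(q), cw, v)


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic sub-stream derived from a root seed and an integer key path."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))
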