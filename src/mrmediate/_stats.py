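"""Small shared numerics: normal tails, CIs, seeded stream splitting."""
from __future__ import annotations

import numpy as np
from scipy import stats

_TINY_P = np.nextafter(0.0, 1.0)


def two_sided_normal_p(z) -> np.ndarray | float:
    """Two-sided p-value for a standard-normal test statistic.

    Clamped into (0, 1] so downstream invariants (p in (0, 1]) hold even for
    extreme z where ``scipy`` underflows to 0.
    """
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, _TINY_P, 1.0)


def normal_ci(beta: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    """Normal-approximation two-sided confidence bounds at level ``alpha``."""
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    return beta - zcrit * se, beta + zcrit * se


def chi2_sf(x, df) -> np.ndarray | float:
    """Upper-tail chi-square probability, clamped into (0, 1]."""
    return np.clip(stats.chi2.sf(x, df), _TINY_P, 1.0)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one seed into ``n`` independent generator streams.

    Uses ``numpy.random.SeedSequence.spawn`` so each stage of a simulation or
    resampling scheme draws from its own stream: adding draws to one stage
    never perturbs another, and the whole scheme is reproducible from the one
    root seed.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]
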