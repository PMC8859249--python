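"""Analytical power for two-sample MR with a binary outcome.

Uses the standard non-centrality approximation: with outcome sample size
n, instrument variance explained r2, case proportion k and causal odds
ratio OR per SD of exposure,

    lambda = n * r2 * k * (1 - k) * ln(OR)^2
    power  = Phi(sqrt(lambda) - z_{1-alpha/2}) + Phi(-sqrt(lambda) - z_{1-alpha/2})
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerInput:
    n: float
    r2: float
    k: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self):
        if not self.n > 0:
            raise ValueError(f"n must be > 0, got {self.n}")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError(f"r2 must be in (0,1), got {self.r2}")
        if not 0.0 < self.k < 1.0:
            raise ValueError(f"k must be in (0,1), got {self.k}")
        if not self.odds_ratio > 0:
            raise ValueError(f"odds_ratio must be > 0, got {self.odds_ratio}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")


def mr_power_binary(p: PowerInput) -> float:
    """Two-sided power of the Wald test under the non-centrality above."""
    lam = p.n * p.r2 * p.k * (1.0 - p.k) * np.log(p.odds_ratio) ** 2
    z_crit = stats.norm.ppf(1.0 - p.alpha / 2.0)
    root = np.sqrt(lam)
    return float(stats.norm.cdf(root - z_crit) + stats.norm.cdf(-root - z_crit))


def mr_power_binary_mc(
    p: PowerInput, n_reps: int = 10_000, seed: int | None = None
) -> float:
    """Monte-Carlo check of :func:`mr_power_binary`.

    Simulates the Wald z-statistic at the same non-centrality
    (z ~ Normal(sqrt(lambda), 1)) and counts two-sided rejections.
    Independent of the closed form's tail arithmetic.
    """
    rng = np.random.default_rng(seed)
    lam = p.n * p.r2 * p.k * (1.0 - p.k) * np.log(p.odds_ratio) ** 2
    z_crit = stats.norm.ppf(1.0 - p.alpha / 2.0)
    z = rng.normal(np.sqrt(lam), 1.0, size=n_reps)
    return float((np.abs(z) > z_crit).mean())
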