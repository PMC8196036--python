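"""Exact operating characteristics of the two-stage analytical-validity
design, and simulation-based power for the rapid-progression comparison.

Analytical validity was judged by whether the composite score could be
successfully calculated in baseline samples: per stage, 32 evaluable
samples, success desired at >=80% (alternative) vs. too low at <=60%
(null).  Rejecting the null when successes >= 24/32 gives exact binomial
error rates alpha = P(X >= 24 | p = 0.60) and beta = P(X <= 23 | p = 0.80).
The two stages are independent, sequential analyses; no error spending is
combined across them.

The trial's clinical design assumed 120 patients split 30/40/30% across
low/intermediate/high score categories with rapid-progression probabilities
0.20/0.34/0.75; power for the 3x2 Fisher exact test at two-sided alpha=0.05
is estimated by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .rapid_progression import clopper_pearson, fisher_exact_rxc


@dataclass(frozen=True)
class StageDesign:
    """One stage of the exact binomial design (defaults: the trial's)."""

    n: int = 32
    cutoff: int = 24
    p_null: float = 0.60
    p_alt: float = 0.80

    def __post_init__(self) -> None:
        if not (0.0 < self.p_null < self.p_alt < 1.0):
            raise ValueError("require 0 < p_null < p_alt < 1")
        if not (0 <= self.cutoff <= self.n):
            raise ValueError("cutoff must be within 0..n")


def stage_alpha(design: StageDesign) -> float:
    """Type-I error: P(X >= cutoff | n, p_null), exact upper binomial tail."""
    return float(stats.binom.sf(design.cutoff - 1, design.n, design.p_null))


def stage_beta(design: StageDesign) -> float:
    """Type-II error: P(X <= cutoff - 1 | n, p_alt), exact lower tail."""
    if design.cutoff == 0:
        return 0.0
    return float(stats.binom.cdf(design.cutoff - 1, design.n, design.p_alt))


def find_cutoff(n: int, p_null: float, p_alt: float,
                alpha_target: float, beta_target: float) -> Optional[int]:
    """Smallest success cutoff meeting the alpha target, if its beta also meets
    the beta target; None when no cutoff satisfies both.

    alpha is decreasing and beta increasing in the cutoff, so the smallest
    cutoff with alpha <= target minimizes beta among admissible cutoffs.
    """
    if not (0 < alpha_target < 1 and 0 < beta_target < 1):
        raise ValueError("targets must lie in (0, 1)")
    for cutoff in range(n + 2):
        if cutoff > n:
            return None
        d = StageDesign(n=n, cutoff=cutoff, p_null=p_null, p_alt=p_alt)
        if stage_alpha(d) <= alpha_target:
            return cutoff if stage_beta(d) <= beta_target else None
    return None


def operating_characteristics(n: int, p_null: float, p_alt: float):
    """(cutoff, alpha, beta) rows over all cutoffs — the design's OC table."""
    rows = []
    for cutoff in range(n + 1):
        d = StageDesign(n=n, cutoff=cutoff, p_null=p_null, p_alt=p_alt)
        rows.append((cutoff, stage_alpha(d), stage_beta(d)))
    return rows


@dataclass(frozen=True)
class PowerSpec:
    """Simulation spec for the Fisher-based rapid-progression power."""

    n_total: int = 120
    group_fracs: tuple[float, float, float] = (0.30, 0.40, 0.30)
    rp_probs: tuple[float, float, float] = (0.20, 0.34, 0.75)
    alpha: float = 0.05
    reps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_fracs) - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")
        if not all(0.0 < p < 1.0 for p in self.rp_probs):
            raise ValueError("RP probabilities must lie in (0, 1)")
        if self.reps < 100:
            raise ValueError("reps must be >= 100")

    @property
    def group_sizes(self) -> tuple[int, ...]:
        return tuple(int(round(f * self.n_total)) for f in self.group_fracs)


@dataclass(frozen=True)
class PowerResult:
    power: float
    mc_ci: tuple[float, float]
    rejections: int
    reps: int


def simulate_rp_power(spec: PowerSpec) -> PowerResult:
    """Monte-Carlo power of the 3x2 Fisher exact test under the design.

    Each replicate draws per-category RP counts binomially at the configured
    sizes and probabilities and tests the 3x2 table at two-sided alpha.
    Deterministic given the seed; the Monte-Carlo CI on the power is exact
    (Clopper-Pearson).
    """
    rng = np.random.default_rng(spec.seed)
    sizes = np.array(spec.group_sizes)
    probs = np.array(spec.rp_probs)
    draws = rng.binomial(sizes, probs, size=(spec.reps, len(sizes)))
    rejections = 0
    for x in draws:
        table = [(int(xi), int(ni - xi)) for xi, ni in zip(x, sizes)]
        if fisher_exact_rxc(table) < spec.alpha:
            rejections += 1
    ci = clopper_pearson(rejections, spec.reps)
    return PowerResult(power=rejections / spec.reps, mc_ci=(ci.lower, ci.upper),
                       rejections=rejections, reps=spec.reps)
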