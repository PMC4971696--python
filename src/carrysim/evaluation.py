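"""Analytic and empirical operating characteristics of the incidence test.

The design's carryover test is a two-sided two-sample z-test comparing the
arms' cumulative incidences.  Given the large-cohort incidences (p1, p2)
the rejection probability at the trial's per-arm sample size n follows the
standard normal-approximation power formula: the critical value uses the
pooled null standard error se0 = sqrt(2*pbar*(1-pbar)/n) with
pbar = (p1+p2)/2, the alternative uses the unpooled
se1 = sqrt((p1*(1-p1) + p2*(1-p2))/n), and both tails are summed,

    power = Phi((-z*se0 - delta)/se1) + 1 - Phi((z*se0 - delta)/se1),

with delta = p1 - p2 and z the upper alpha/2 normal quantile, so that
p1 == p2 returns exactly alpha.  When the simulated carryover duration is
zero this rejection probability IS the design's Type I error rate for the
carryover hypothesis; with carryover present it is the power.

``empirical_rejection_rate`` cross-validates the analytic shortcut by
simulating many replicate trials at the test sample size and running the
pooled two-proportion z-test on each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trial_designs import (
    ArmResult,
    ConfigError,
    TrialConfig,
    as_generator,
    contrast_indices,
    design_assignments,
    run_design,
    simulate_arm_outcomes,
)

__all__ = [
    "TestResult",
    "power_two_proportions",
    "two_proportion_reject",
    "analytic_test",
    "type_i_error",
    "empirical_rejection_rate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """Arm incidences and the analytic rejection probability at size n."""

    p1: float
    p2: float
    difference: float
    n_per_arm: int
    alpha: float
    rejection_probability: float

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "rejection_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.difference - (self.p1 - self.p2)) > 1e-12:
            raise ValueError("difference must equal p1 - p2")


def power_two_proportions(p1: float, p2: float, n_per_arm: int, alpha: float) -> float:
    """Two-sided rejection probability of the two-sample proportion z-test.

    Normal approximation, pooled-variance critical value, unpooled-variance
    alternative, both tails summed (so the null p1 == p2 returns exactly
    alpha); no continuity correction.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("p1 and p2 must be in [0, 1]")
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = float(n_per_arm)
    pbar = (p1 + p2) / 2.0
    se0 = np.sqrt(2.0 * pbar * (1.0 - pbar) / n)
    se1 = np.sqrt((p1 * (1.0 - p1) + p2 * (1.0 - p2)) / n)
    delta = p1 - p2
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    if se1 == 0.0:
        if p1 == p2:
            # Both incidences degenerate at 0 or 1: the test statistic is
            # undefined and no rejection is possible.
            logger.warning("degenerate incidences p1 == p2 == %s; rejection impossible", p1)
            return 0.0
        return 1.0 if abs(delta) > z * se0 else 0.0
    lo = stats.norm.cdf((-z * se0 - delta) / se1)
    hi = stats.norm.sf((z * se0 - delta) / se1)
    return float(lo + hi)


def two_proportion_reject(x1, x2, n_per_arm: int, alpha: float):
    """Vectorised pooled two-proportion z-test: does each replicate reject?

    ``x1``, ``x2`` are diagnosed counts out of ``n_per_arm`` per arm.
    Replicates with a degenerate pooled proportion (0 or 1) never reject.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = float(n_per_arm)
    pooled = (x1 + x2) / (2.0 * n)
    se = np.sqrt(np.clip(2.0 * pooled * (1.0 - pooled) / n, 0.0, None))
    safe = np.where(se > 0, se, 1.0)
    zstat = np.where(se > 0, (x1 - x2) / n / safe, 0.0)
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return np.abs(zstat) > crit


def analytic_test(
    config: TrialConfig, rng: np.random.Generator | int | None = None
) -> TestResult:
    """Simulate large cohorts, then convert incidences to a rejection probability."""
    rng = as_generator(rng)
    arms = run_design(config, rng)
    i, j = contrast_indices(config.design)
    p1, p2 = arms[i].cumulative_incidence, arms[j].cumulative_incidence
    return TestResult(
        p1=p1,
        p2=p2,
        difference=p1 - p2,
        n_per_arm=config.n_per_arm_for_test,
        alpha=config.alpha,
        rejection_probability=power_two_proportions(
            p1, p2, config.n_per_arm_for_test, config.alpha
        ),
    )


def type_i_error(config: TrialConfig, rng: np.random.Generator | int | None = None) -> TestResult:
    """The design's Type I error for the carryover hypothesis (requires zero carryover)."""
    if config.carryover_years != 0:
        raise ConfigError(
            "carryover_years",
            "Type I error is defined under zero carryover; set carryover_years=0",
        )
    return analytic_test(config, rng)


def empirical_rejection_rate(
    config: TrialConfig,
    n_replicates: int,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Rejection fraction over replicate trials at the test sample size.

    Each replicate simulates fresh cohorts of ``n_per_arm_for_test`` subjects
    per arm and applies the pooled two-proportion z-test.  Replicates are
    batched (contiguous blocks of iid subjects form valid replicate arms) so
    the noise matrices stay modest in memory.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = as_generator(rng)
    n_test = config.n_per_arm_for_test
    n_times = max(1, int(np.floor(config.horizon / config.measurement_interval + 1e-9)))
    # ~2e7 gaussians per batch per arm keeps peak memory in the low hundreds of MB.
    batch = max(1, int(2e7 / (n_test * n_times)))
    assignments = design_assignments(config)
    i, j = contrast_indices(config.design)
    n_reject = 0
    done = 0
    while done < n_replicates:
        k = min(batch, n_replicates - done)
        counts = []
        for arm_index in (i, j):
            _, assignment = assignments[arm_index]
            _, idx = simulate_arm_outcomes(config, assignment, rng, k * n_test)
            diagnosed = (idx >= 0).reshape(k, n_test)
            counts.append(diagnosed.sum(axis=1))
        n_reject += int(np.sum(two_proportion_reject(counts[0], counts[1], n_test, config.alpha)))
        done += k
    return n_reject / n_replicates
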