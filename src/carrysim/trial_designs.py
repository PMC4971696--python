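"""Cohort simulation of parallel-group, crossover and combination designs.

Each arm is a cohort of independent subjects sharing a treatment schedule.
Subjects are censored at first diagnosis (they switch to open-label
treatment, so later measurements are never used), and an arm's cumulative
incidence is the fraction diagnosed by the end of the study horizon.

Designs:

- ``parallel``: treatment arm on drug for ``treatment_years`` then followed
  untreated (plus any carryover) for ``followup_years``; control arm never
  treated.
- ``crossover``: two periods of ``period_years``; one arm treated in the
  first period, the other in the second.
- ``combination``: the crossover's two arms plus a never-treated arm, a
  three-arm design meant to let the parallel design's positive bias and the
  crossover's negative bias cancel.

Measurements taken exactly at a period boundary count as under the
treatment of the period they conclude (the blood draw at a crossover visit
happens before the switch), hence ``boundary_on_treatment=True`` on every
design-layer assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .diagnosis import RULE_IDS, DiagnosisRule, first_diagnosis_indices
from .trajectory_model import (
    TreatmentAssignment,
    carryover_weight,
    measurement_times,
    on_treatment,
)

__all__ = [
    "DESIGNS",
    "ConfigError",
    "TrialConfig",
    "ArmResult",
    "design_assignments",
    "contrast_indices",
    "simulate_arm_outcomes",
    "run_parallel",
    "run_crossover",
    "run_combination",
    "run_design",
    "as_generator",
]

DESIGNS = ("parallel", "crossover", "combination")


class ConfigError(ValueError):
    """Invalid trial configuration; carries a field-level message."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class TrialConfig:
    """One scenario's full parameterisation.

    Defaults follow the motivating prevention-trial setting: prehypertensive
    inclusion window 125-140 mm Hg, 1 mm Hg/yr upward trend, 5 mm Hg
    measurement SD, -10 mm Hg treatment effect, two years of treatment with
    two further years of follow-up, 3-monthly visits, two-consecutive-above
    diagnosis rule, and a two-proportion test at 405 subjects per arm
    (about half of the motivating trial's 809 randomised) at alpha 0.05.
    """

    design: str = "parallel"
    rule: str = "two_consecutive"
    threshold: float = 140.0
    treatment_years: float = 2.0
    followup_years: float = 2.0
    period_years: float = 2.0
    measurement_interval: float = 0.25
    inclusion_low: float = 125.0
    inclusion_high: float = 140.0
    trend: float = 1.0
    slope_sd: float = 0.0
    noise_sd: float = 5.0
    treatment_effect: float = -10.0
    carryover_effect: float | None = None
    carryover_years: float = 0.0
    cohort_size_per_arm: int = 100_000
    n_per_arm_for_test: int = 405
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.design not in DESIGNS:
            raise ConfigError("design", f"must be one of {DESIGNS}, got {self.design!r}")
        if self.rule not in RULE_IDS:
            raise ConfigError("rule", f"must be one of {RULE_IDS}, got {self.rule!r}")
        if self.threshold <= 0:
            raise ConfigError("threshold", "must be > 0")
        for name in ("treatment_years", "followup_years", "period_years", "measurement_interval"):
            if getattr(self, name) <= 0:
                raise ConfigError(name, f"must be > 0, got {getattr(self, name)}")
        if self.inclusion_low >= self.inclusion_high:
            raise ConfigError(
                "inclusion_low",
                f"must be < inclusion_high, got ({self.inclusion_low}, {self.inclusion_high})",
            )
        for name in ("noise_sd", "slope_sd", "carryover_years"):
            if getattr(self, name) < 0:
                raise ConfigError(name, f"must be >= 0, got {getattr(self, name)}")
        for name in ("cohort_size_per_arm", "n_per_arm_for_test"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(name, f"must be >= 1, got {getattr(self, name)}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha", f"must be in (0, 1), got {self.alpha}")

    @property
    def horizon(self) -> float:
        """Total study length in years for this design."""
        if self.design == "parallel":
            return self.treatment_years + self.followup_years
        return 2.0 * self.period_years

    def diagnosis_rule(self) -> DiagnosisRule:
        return DiagnosisRule(rule_id=self.rule, threshold=self.threshold)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_overrides(self, **kwargs) -> "TrialConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ArmResult:
    """Cumulative-incidence summary for one simulated arm."""

    arm_label: str
    n_simulated: int
    n_diagnosed: int
    cumulative_incidence: float
    diagnosis_times: np.ndarray
    n_diagnosed_by_period: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_diagnosed != len(self.diagnosis_times):
            raise ValueError("n_diagnosed must equal len(diagnosis_times)")
        expected = self.n_diagnosed / self.n_simulated
        if abs(self.cumulative_incidence - expected) > 1e-12:
            raise ValueError("cumulative_incidence must equal n_diagnosed / n_simulated")


def as_generator(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Accept a Generator, a seed, or None (fresh OS entropy)."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def design_assignments(config: TrialConfig) -> list[tuple[str, TreatmentAssignment]]:
    """The (label, treatment schedule) of each arm of the configured design."""
    d = config.carryover_years
    if config.design == "parallel":
        return [
            (
                "treatment",
                TreatmentAssignment(((0.0, config.treatment_years),), d, boundary_on_treatment=True),
            ),
            ("control", TreatmentAssignment((), d, boundary_on_treatment=True)),
        ]
    p = config.period_years
    first = ("treatment_first", TreatmentAssignment(((0.0, p),), d, boundary_on_treatment=True))
    second = (
        "treatment_second",
        TreatmentAssignment(((p, 2.0 * p),), d, boundary_on_treatment=True),
    )
    if config.design == "crossover":
        return [first, second]
    never = ("never_treated", TreatmentAssignment((), d, boundary_on_treatment=True))
    return [first, never, second]


def contrast_indices(design: str) -> tuple[int, int]:
    """Which two arms' incidence difference tests for carryover."""
    return (0, 2) if design == "combination" else (0, 1)


def simulate_arm_outcomes(
    config: TrialConfig,
    assignment: TreatmentAssignment,
    rng: np.random.Generator,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised cohort simulation of one arm.

    Returns ``(times, idx)`` where ``idx[i]`` is subject i's first
    diagnosing visit (0-based; -1 if never diagnosed).  Draw layout is
    fixed for reproducibility: intercepts, then slopes (only when
    slope_sd > 0), then the full noise matrix; subject i always owns row i.
    """
    times = measurement_times(config.measurement_interval, config.horizon)
    x = np.asarray(on_treatment(times, assignment), dtype=float)
    z = np.asarray(carryover_weight(times, assignment), dtype=float)
    c = config.treatment_effect
    d = c if config.carryover_effect is None else config.carryover_effect

    a = rng.uniform(config.inclusion_low, config.inclusion_high, size=n)
    if config.slope_sd > 0:
        b = config.trend + config.slope_sd * rng.standard_normal(n)
    else:
        b = np.full(n, float(config.trend))
    underlying = a[:, None] + b[:, None] * times[None, :] + c * x + d * z
    if config.noise_sd > 0:
        measured = underlying + config.noise_sd * rng.standard_normal((n, len(times)))
    else:
        measured = underlying

    rule = config.diagnosis_rule()
    idx = first_diagnosis_indices(
        rule, measured, underlying if rule.rule_id == "oracle" else None
    )
    return times, idx


def _simulate_arm(
    config: TrialConfig,
    assignment: TreatmentAssignment,
    label: str,
    rng: np.random.Generator,
    n: int | None = None,
) -> ArmResult:
    n = int(config.cohort_size_per_arm if n is None else n)
    times, idx = simulate_arm_outcomes(config, assignment, rng, n)
    diag_times = times[idx[idx >= 0]]
    n_diag = int(len(diag_times))
    return ArmResult(
        arm_label=label,
        n_simulated=n,
        n_diagnosed=n_diag,
        cumulative_incidence=n_diag / n,
        diagnosis_times=diag_times,
    )


def _with_period_counts(arm: ArmResult, period_years: float) -> ArmResult:
    in_p1 = int(np.sum(arm.diagnosis_times <= period_years))
    counts = (in_p1, arm.n_diagnosed - in_p1)
    return ArmResult(
        arm_label=arm.arm_label,
        n_simulated=arm.n_simulated,
        n_diagnosed=arm.n_diagnosed,
        cumulative_incidence=arm.cumulative_incidence,
        diagnosis_times=arm.diagnosis_times,
        n_diagnosed_by_period=counts,
    )


def _run(
    config: TrialConfig,
    design: str,
    rng: np.random.Generator | int | None,
    n_per_arm: int | None,
) -> list[ArmResult]:
    if config.design != design:
        raise ConfigError("design", f"expected design={design!r}, got {config.design!r}")
    rng = as_generator(rng)
    arms = [
        _simulate_arm(config, assignment, label, rng, n_per_arm)
        for label, assignment in design_assignments(config)
    ]
    if design != "parallel":
        arms = [_with_period_counts(arm, config.period_years) for arm in arms]
    return arms


def run_parallel(
    config: TrialConfig,
    rng: np.random.Generator | int | None = None,
    n_per_arm: int | None = None,
) -> list[ArmResult]:
    """Parallel-group design: (treatment, control) cumulative incidences."""
    return _run(config, "parallel", rng, n_per_arm)


def run_crossover(
    config: TrialConfig,
    rng: np.random.Generator | int | None = None,
    n_per_arm: int | None = None,
) -> list[ArmResult]:
    """Two-period crossover: (treatment-first, treatment-second) arms.

    Subjects diagnosed in period 1 are censored and contribute no period-2
    data; per-period event counts are attached to each arm.
    """
    return _run(config, "crossover", rng, n_per_arm)


def run_combination(
    config: TrialConfig,
    rng: np.random.Generator | int | None = None,
    n_per_arm: int | None = None,
) -> list[ArmResult]:
    """Three-arm combination: treatment-first, never-treated, treatment-second."""
    return _run(config, "combination", rng, n_per_arm)


_RUNNERS = {
    "parallel": run_parallel,
    "crossover": run_crossover,
    "combination": run_combination,
}


def run_design(
    config: TrialConfig,
    rng: np.random.Generator | int | None = None,
    n_per_arm: int | None = None,
) -> list[ArmResult]:
    """Dispatch on ``config.design``."""
    return _RUNNERS[config.design](config, rng, n_per_arm)
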