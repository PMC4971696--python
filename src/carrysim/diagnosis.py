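"""Threshold-based rules for diagnosing incident hypertension.

Six rules, all against a single systolic threshold (140 mm Hg by default,
"above" meaning strictly greater):

- ``single``: one measurement above.
- ``two_consecutive``: two consecutive measurements above.
- ``mean_two``: the mean of two consecutive measurements above.
- ``any_three``: any three measurements above, not necessarily consecutive,
  accumulated over the subject's whole observed series (across treatment,
  post-treatment and crossover periods); diagnosis at the third exceedance.
- ``mean_three``: the mean of three consecutive measurements above.
- ``oracle``: the measured AND the underlying (noise-free) value are both
  above at the same visit.  Infeasible in practice — it requires knowing the
  long-term average — but it isolates the contribution of measurement noise
  to false diagnosis.

Each rule returns the earliest visit at which its condition first holds;
the subject is censored there (switched to open-label treatment), so no
later measurement is ever used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_model import MeasurementSeries

__all__ = [
    "RULE_IDS",
    "FEASIBLE_RULE_IDS",
    "DiagnosisRule",
    "DiagnosisOutcome",
    "apply_rule",
    "first_diagnosis_indices",
]

#: Stable identifiers accepted in configs and on the command line.
RULE_IDS = ("single", "two_consecutive", "mean_two", "any_three", "mean_three", "oracle")

#: Rules implementable in a real trial (everything except the oracle).
FEASIBLE_RULE_IDS = RULE_IDS[:-1]


@dataclass(frozen=True)
class DiagnosisRule:
    rule_id: str
    threshold: float = 140.0

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_IDS:
            raise ValueError(f"unknown rule_id {self.rule_id!r}; choose from {RULE_IDS}")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass(frozen=True)
class DiagnosisOutcome:
    """Whether/when a subject is diagnosed.  Indices are 0-based into times."""

    diagnosed: bool
    diagnosis_index: int | None
    diagnosis_time: float | None

    def __post_init__(self) -> None:
        has_idx = self.diagnosis_index is not None
        has_time = self.diagnosis_time is not None
        if self.diagnosed != has_idx or self.diagnosed != has_time:
            raise ValueError("diagnosed must match presence of index and time")


def _condition_matrix(
    rule: DiagnosisRule, measured: np.ndarray, underlying: np.ndarray | None
) -> np.ndarray:
    """Boolean (n_subjects, n_times) matrix: rule condition holds at visit k."""
    thr = rule.threshold
    above = measured > thr
    n, t = measured.shape
    cond = np.zeros((n, t), dtype=bool)
    if rule.rule_id == "single":
        cond = above
    elif rule.rule_id == "two_consecutive":
        cond[:, 1:] = above[:, 1:] & above[:, :-1]
    elif rule.rule_id == "mean_two":
        cond[:, 1:] = (measured[:, 1:] + measured[:, :-1]) / 2.0 > thr
    elif rule.rule_id == "any_three":
        cond = above & (np.cumsum(above, axis=1) >= 3)
    elif rule.rule_id == "mean_three":
        if t >= 3:
            win = measured[:, 2:] + measured[:, 1:-1] + measured[:, :-2]
            cond[:, 2:] = win / 3.0 > thr
    elif rule.rule_id == "oracle":
        if underlying is None:
            raise ValueError("oracle rule requires underlying (noise-free) values")
        cond = above & (underlying > thr)
    else:  # pragma: no cover - guarded by DiagnosisRule
        raise ValueError(f"unknown rule {rule.rule_id!r}")
    return cond


def first_diagnosis_indices(
    rule: DiagnosisRule,
    measured: np.ndarray,
    underlying: np.ndarray | None = None,
) -> np.ndarray:
    """Earliest diagnosing visit per subject for a (n_subjects, n_times) block.

    Returns an int array with -1 for subjects never diagnosed.  Measurements
    after the first diagnosis are irrelevant by construction (the scan is for
    the earliest hit), which implements censoring at diagnosis.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.ndim != 2 or measured.shape[1] == 0:
        raise ValueError("measured must be a non-empty 2-d array (subjects x times)")
    cond = _condition_matrix(rule, measured, underlying)
    hit = cond.any(axis=1)
    idx = cond.argmax(axis=1)
    return np.where(hit, idx, -1)


def apply_rule(rule: DiagnosisRule, series: MeasurementSeries) -> DiagnosisOutcome:
    """Apply a diagnosis rule to one subject's series; earliest hit wins."""
    if len(series) == 0:
        raise ValueError("series must be non-empty")
    underlying = series.underlying[None, :] if rule.rule_id == "oracle" else None
    idx = int(first_diagnosis_indices(rule, series.measured[None, :], underlying)[0])
    if idx < 0:
        return DiagnosisOutcome(diagnosed=False, diagnosis_index=None, diagnosis_time=None)
    return DiagnosisOutcome(
        diagnosed=True, diagnosis_index=idx, diagnosis_time=float(series.times[idx])
    )
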