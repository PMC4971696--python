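"""Latent longitudinal blood-pressure trajectories with treatment and carryover.

A subject's systolic blood pressure at time ``t`` (years) is modelled as a
long-term linear trend plus an additive on-treatment effect, an additive
carryover effect that decays linearly after treatment stops, and i.i.d.
Gaussian measurement / intra-individual noise:

    Y(t) = a + b*t + c*X(t) + d*Z(t) + eps(t)

where ``X(t)`` is the on-treatment indicator and ``Z(t)`` the carryover
weight, which jumps to 1 when treatment stops and decays linearly to 0 over
the carryover duration ``D``.  Baseline intercepts are drawn uniformly over
the trial's inclusion window because entry into a prevention trial is itself
conditioned on a blood-pressure threshold.

By default the on-treatment indicator uses half-open intervals
``[start, stop)``: at the stop time the subject is already off treatment and
the carryover weight is exactly 1.  Trial designs instead evaluate
measurements taken exactly at a period boundary as reflecting the treatment
of the period they conclude (``boundary_on_treatment=True``), because the
measurement at a crossover visit is taken before the switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubjectParams",
    "TreatmentAssignment",
    "MeasurementSeries",
    "sample_subject",
    "on_treatment",
    "carryover_weight",
    "true_bp",
    "measurement_times",
    "simulate_series",
    "trajectory_frame",
]


@dataclass(frozen=True)
class SubjectParams:
    """Latent trajectory coefficients for one simulated participant.

    Units: mm Hg for ``intercept_a``, ``treatment_effect_c``,
    ``carryover_effect_d`` and ``noise_sd``; mm Hg per year for ``slope_b``.
    A negative treatment effect lowers blood pressure while on treatment;
    the carryover effect is scaled by the carryover weight after cessation.
    """

    intercept_a: float
    slope_b: float
    treatment_effect_c: float
    carryover_effect_d: float
    noise_sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept_a):
            raise ValueError("intercept_a must be finite")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class TreatmentAssignment:
    """On/off-treatment schedule and carryover duration for one arm.

    ``treatment_intervals`` are disjoint, ordered ``(start, stop)`` pairs in
    years during which the subject is on active treatment.  After each stop
    the carryover weight decays from 1 to 0 over ``carryover_duration``
    years (zero duration means no carryover at all).

    ``boundary_on_treatment`` controls the status of a measurement taken
    exactly at a stop time: ``False`` (default) means half-open intervals,
    the subject is off treatment and the carryover weight is 1 there;
    ``True`` means the boundary visit still reflects the treatment just
    received, and carryover decay starts strictly after the stop.
    """

    treatment_intervals: tuple[tuple[float, float], ...]
    carryover_duration: float
    boundary_on_treatment: bool = False

    def __post_init__(self) -> None:
        ivs = tuple((float(s), float(e)) for s, e in self.treatment_intervals)
        object.__setattr__(self, "treatment_intervals", ivs)
        if self.carryover_duration < 0:
            raise ValueError("carryover_duration must be >= 0")
        prev_end = 0.0
        for k, (s, e) in enumerate(ivs):
            if s < 0 or e < 0:
                raise ValueError("interval endpoints must be >= 0")
            if e <= s:
                raise ValueError(f"interval {k} has stop <= start: {(s, e)}")
            if k > 0 and s < prev_end:
                raise ValueError("treatment intervals must be disjoint and ordered")
            prev_end = e


@dataclass(frozen=True)
class MeasurementSeries:
    """Measurement times with measured (noisy) and underlying (noise-free) BP."""

    times: np.ndarray
    measured: np.ndarray
    underlying: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.measured, dtype=float)
        u = np.asarray(self.underlying, dtype=float)
        if not (t.ndim == m.ndim == u.ndim == 1):
            raise ValueError("times, measured, underlying must be 1-d")
        if not (len(t) == len(m) == len(u)):
            raise ValueError("times, measured, underlying must have equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "measured", m)
        object.__setattr__(self, "underlying", u)

    def __len__(self) -> int:
        return len(self.times)


def sample_subject(
    inclusion_low: float,
    inclusion_high: float,
    trend: float,
    slope_sd: float,
    treatment_effect: float,
    noise_sd: float,
    rng: np.random.Generator,
    carryover_effect: float | None = None,
) -> SubjectParams:
    """Draw one subject's latent coefficients.

    The intercept is uniform over ``[inclusion_low, inclusion_high)`` (the
    trial's screening window), the slope is ``Normal(trend, slope_sd**2)``
    (degenerate at ``trend`` when ``slope_sd == 0``), and the treatment
    effect is fixed.  The carryover magnitude defaults to the treatment
    effect, so blood pressure returns to its long-term trend continuously
    from the full on-treatment level.
    """
    if inclusion_low >= inclusion_high:
        raise ValueError(
            f"inclusion_low must be < inclusion_high, got ({inclusion_low}, {inclusion_high})"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if slope_sd < 0:
        raise ValueError("slope_sd must be >= 0")
    a = float(rng.uniform(inclusion_low, inclusion_high))
    b = float(trend + slope_sd * rng.standard_normal()) if slope_sd > 0 else float(trend)
    d = float(treatment_effect if carryover_effect is None else carryover_effect)
    return SubjectParams(
        intercept_a=a,
        slope_b=b,
        treatment_effect_c=float(treatment_effect),
        carryover_effect_d=d,
        noise_sd=float(noise_sd),
    )


def on_treatment(t, assignment: TreatmentAssignment):
    """On-treatment indicator X(t); vectorised over ``t``."""
    t_arr = np.asarray(t, dtype=float)
    x = np.zeros(t_arr.shape, dtype=bool)
    for start, stop in assignment.treatment_intervals:
        if assignment.boundary_on_treatment:
            x |= (t_arr >= start) & (t_arr <= stop)
        else:
            x |= (t_arr >= start) & (t_arr < stop)
    return x if t_arr.ndim else bool(x)


def carryover_weight(t, assignment: TreatmentAssignment):
    """Carryover weight Z(t) in [0, 1]; vectorised over ``t``.

    Zero while on treatment and before the first treatment stop; after a
    stop at ``t_stop`` it equals ``max(0, 1 - (t - t_stop) / D)`` where
    ``D`` is the carryover duration (identically zero when ``D == 0``).
    A later treatment interval resets the weight.
    """
    t_arr = np.asarray(t, dtype=float)
    z = np.zeros(t_arr.shape, dtype=float)
    d = assignment.carryover_duration
    if d > 0 and assignment.treatment_intervals:
        last_stop = np.full(t_arr.shape, np.nan)
        for _, stop in assignment.treatment_intervals:
            past = t_arr > stop if assignment.boundary_on_treatment else t_arr >= stop
            last_stop = np.where(past, stop, last_stop)
        off = ~np.asarray(on_treatment(t_arr, assignment), dtype=bool)
        with np.errstate(invalid="ignore", over="ignore"):
            w = np.clip(1.0 - (t_arr - last_stop) / d, 0.0, 1.0)
        z = np.where(off & ~np.isnan(last_stop), w, 0.0)
    return z if t_arr.ndim else float(z)


def true_bp(params: SubjectParams, t, assignment: TreatmentAssignment):
    """Noise-free blood pressure a + b*t + c*X(t) + d*Z(t); vectorised over t."""
    t_arr = np.asarray(t, dtype=float)
    x = np.asarray(on_treatment(t_arr, assignment), dtype=float)
    z = np.asarray(carryover_weight(t_arr, assignment), dtype=float)
    y = (
        params.intercept_a
        + params.slope_b * t_arr
        + params.treatment_effect_c * x
        + params.carryover_effect_d * z
    )
    return y if t_arr.ndim else float(y)


def measurement_times(interval: float, horizon: float) -> np.ndarray:
    """Visit times k*interval for k = 1 .. floor(horizon/interval).

    The screening measurement at t = 0 is the inclusion draw and is excluded
    from the diagnostic series (inclusion conditions on being below the
    threshold, so it could never diagnose anyone).
    """
    if interval <= 0:
        raise ValueError("measurement interval must be > 0")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    n = int(np.floor(horizon / interval + 1e-9))
    return interval * np.arange(1, n + 1, dtype=float)


def simulate_series(
    params: SubjectParams,
    schedule: float,
    horizon: float,
    assignment: TreatmentAssignment,
    rng: np.random.Generator,
) -> MeasurementSeries:
    """Simulate one subject's noisy measurement series on a regular schedule."""
    times = measurement_times(schedule, horizon)
    underlying = np.asarray(true_bp(params, times, assignment), dtype=float)
    if params.noise_sd > 0:
        measured = underlying + params.noise_sd * rng.standard_normal(len(times))
    else:
        measured = underlying.copy()
    return MeasurementSeries(times=times, measured=measured, underlying=underlying)


def trajectory_frame(
    series: MeasurementSeries,
    assignment: TreatmentAssignment,
    subject_id: int,
    arm: str,
) -> pd.DataFrame:
    """Long-format per-visit dump of one subject's trajectory."""
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "arm": arm,
            "time_years": series.times,
            "measured_bp": series.measured,
            "underlying_bp": series.underlying,
            "on_treatment": np.asarray(on_treatment(series.times, assignment), dtype=int),
            "carryover_weight": np.asarray(carryover_weight(series.times, assignment)),
        }
    )
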