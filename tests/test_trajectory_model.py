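"""Trajectory model: subject sampling, carryover decay, noise-free BP, series."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from carrysim import (
    MeasurementSeries,
    SubjectParams,
    TreatmentAssignment,
    carryover_weight,
    measurement_times,
    on_treatment,
    sample_subject,
    simulate_series,
    true_bp,
)


@pytest.fixture
def stop2_assignment():
    return TreatmentAssignment(((0.0, 2.0),), carryover_duration=2.0)


class TestSampleSubject:
    def test_prehypertensive_draw(self, rng):
        p = sample_subject(125, 140, trend=1, slope_sd=0, treatment_effect=-10, noise_sd=5, rng=rng)
        assert 125 <= p.intercept_a < 140
        assert p.slope_b == 1.0
        assert p.treatment_effect_c == -10.0
        assert p.carryover_effect_d == -10.0  # defaults to the treatment effect
        assert p.noise_sd == 5.0

    def test_degenerate_range(self, rng):
        p = sample_subject(130, 130 + 1e-9, 0, 0, 0, 0, rng)
        assert p.intercept_a == pytest.approx(130, abs=1e-8)
        assert p.slope_b == 0 and p.treatment_effect_c == 0 and p.carryover_effect_d == 0

    def test_intercept_mean_matches_uniform(self, rng):
        draws = [sample_subject(110, 140, 1, 0, -5, 5, rng).intercept_a for _ in range(10_000)]
        # closed-form mean of Unif(110, 140) is 125; MC SE ~ 30/sqrt(12)/100 ~ 0.087
        assert np.mean(draws) == pytest.approx(125.0, abs=0.5)

    def test_explicit_carryover_magnitude(self, rng):
        p = sample_subject(125, 140, 1, 0, -10, 5, rng, carryover_effect=-4.0)
        assert p.carryover_effect_d == -4.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(inclusion_low=140, inclusion_high=125),
            dict(noise_sd=-1.0),
            dict(slope_sd=-0.5),
        ],
    )
    def test_invalid_inputs(self, rng, kwargs):
        base = dict(
            inclusion_low=125, inclusion_high=140, trend=1, slope_sd=0,
            treatment_effect=-10, noise_sd=5, rng=rng,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            sample_subject(**base)


class TestCarryoverWeight:
    def test_piecewise_linear_decay(self, stop2_assignment):
        # starts at 1 at the stop, linear to 0 over the carryover duration
        assert carryover_weight(2.0, stop2_assignment) == 1.0
        assert carryover_weight(3.0, stop2_assignment) == 0.5
        assert carryover_weight(4.0, stop2_assignment) == 0.0
        assert carryover_weight(7.0, stop2_assignment) == 0.0

    def test_zero_before_and_during_treatment(self):
        a = TreatmentAssignment(((1.0, 2.0),), 2.0)
        assert carryover_weight(0.5, a) == 0.0
        assert carryover_weight(1.5, a) == 0.0

    def test_zero_duration_means_no_carryover(self):
        a = TreatmentAssignment(((0.0, 2.0),), 0.0)
        assert all(carryover_weight(t, a) == 0.0 for t in (2.0, 2.01, 3.0, 10.0))

    def test_retreatment_resets_weight(self):
        a = TreatmentAssignment(((0.0, 1.0), (2.0, 3.0)), 2.0)
        assert carryover_weight(1.5, a) == 0.75  # decaying from first stop
        assert carryover_weight(2.5, a) == 0.0  # back on treatment
        assert carryover_weight(3.5, a) == 0.75  # decaying from second stop

    def test_boundary_on_treatment_convention(self):
        a = TreatmentAssignment(((0.0, 2.0),), 2.0, boundary_on_treatment=True)
        assert on_treatment(2.0, a)
        assert carryover_weight(2.0, a) == 0.0
        assert carryover_weight(3.0, a) == 0.5

    @given(
        t=st.floats(0, 20),
        stop=st.floats(0.5, 5),
        duration=st.floats(0, 5),
    )
    def test_weight_in_unit_interval_and_zero_on_treatment(self, t, stop, duration):
        a = TreatmentAssignment(((0.0, stop),), duration)
        z = carryover_weight(t, a)
        assert 0.0 <= z <= 1.0
        if on_treatment(t, a):
            assert z == 0.0

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            TreatmentAssignment(((2.0, 1.0),), 0.0)
        with pytest.raises(ValueError):
            TreatmentAssignment(((0.0, 2.0), (1.0, 3.0)), 0.0)
        with pytest.raises(ValueError):
            TreatmentAssignment(((0.0, 1.0),), -1.0)


class TestTrueBP:
    def test_on_treatment_value(self):
        p = SubjectParams(139, 1, -5, -5, 0)
        a = TreatmentAssignment(((0.0, 2.0),), 2.0)
        assert true_bp(p, 1.0, a) == pytest.approx(135.0)

    def test_linear_decay_value(self):
        p = SubjectParams(139, 1, -5, -5, 0)
        a = TreatmentAssignment(((0.0, 2.0),), 2.0)
        # a + b*t + d*Z = 139 + 3 - 5*0.5
        assert true_bp(p, 3.0, a) == pytest.approx(139.5)

    def test_untreated_identity(self):
        p = SubjectParams(131, 2, 0, 0, 0)
        a = TreatmentAssignment((), 1.0)
        for t in (0.0, 1.3, 7.0):
            assert true_bp(p, t, a) == pytest.approx(131 + 2 * t)

    @given(stop=st.floats(0.5, 4), duration=st.floats(0.1, 3), effect=st.floats(-15, -1))
    def test_continuous_at_stop_when_carryover_equals_treatment_effect(
        self, stop, duration, effect
    ):
        p = SubjectParams(132, 1, effect, effect, 0)
        a = TreatmentAssignment(((0.0, stop),), duration)
        h = 1e-7
        left = true_bp(p, stop - h, a)
        at = true_bp(p, stop, a)
        right = true_bp(p, stop + h, a)
        assert abs(left - at) < 1e-4 and abs(right - at) < 1e-4


class TestSimulateSeries:
    def test_visit_count_and_times(self, rng):
        p = SubjectParams(130, 1, 0, 0, 0)
        s = simulate_series(p, 0.25, 4.0, TreatmentAssignment((), 0.0), rng)
        assert len(s) == 16
        np.testing.assert_allclose(s.times, 0.25 * np.arange(1, 17))

    def test_noise_free_equals_underlying(self, rng):
        p = SubjectParams(130, 1, -5, -5, 0)
        s = simulate_series(p, 0.5, 4.0, TreatmentAssignment(((0.0, 2.0),), 1.0), rng)
        np.testing.assert_array_equal(s.measured, s.underlying)

    def test_noise_sd_recovered(self, rng):
        p = SubjectParams(130, 0, 0, 0, 5.0)
        resid = np.concatenate(
            [
                simulate_series(p, 0.5, 2.0, TreatmentAssignment((), 0.0), rng).measured - 130
                for _ in range(2500)
            ]
        )
        assert np.std(resid) == pytest.approx(5.0, rel=0.03)

    def test_fixed_seed_is_bit_identical(self):
        p = SubjectParams(132, 1, -10, -10, 5)
        a = TreatmentAssignment(((0.0, 2.0),), 1.0)
        s1 = simulate_series(p, 0.25, 4.0, a, np.random.default_rng(7))
        s2 = simulate_series(p, 0.25, 4.0, a, np.random.default_rng(7))
        np.testing.assert_array_equal(s1.measured, s2.measured)

    def test_constant_when_no_noise_trend_or_treatment(self, rng):
        p = SubjectParams(128, 0, 0, 0, 0)
        s = simulate_series(p, 1.0, 5.0, TreatmentAssignment(((0.0, 2.0),), 2.0), rng)
        np.testing.assert_allclose(s.measured, 128.0)

    def test_invalid_schedule_or_horizon(self, rng):
        p = SubjectParams(130, 0, 0, 0, 0)
        a = TreatmentAssignment((), 0.0)
        with pytest.raises(ValueError):
            simulate_series(p, 0.0, 4.0, a, rng)
        with pytest.raises(ValueError):
            simulate_series(p, 0.25, -1.0, a, rng)

    def test_series_validation(self):
        with pytest.raises(ValueError):
            MeasurementSeries(times=[1.0, 1.0], measured=[1, 2], underlying=[1, 2])
        with pytest.raises(ValueError):
            MeasurementSeries(times=[1.0, 2.0], measured=[1], underlying=[1, 2])


def test_measurement_times_excludes_screening_visit():
    times = measurement_times(0.5, 3.0)
    assert times[0] == 0.5 and 0.0 not in times and times[-1] == 3.0
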