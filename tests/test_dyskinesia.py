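"""Gating, 1-4 Hz scoring and minute/period aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onoff.dyskinesia import (
    ABSENT,
    ANALYZABLE,
    POSTURAL_TRANSITION,
    PRESENT,
    UNDETERMINED,
    WALKING,
    MinuteDyskStatus,
    SegmentDyskStatus,
    aggregate_minute,
    aggregate_period,
    gate_segment,
    period_dysk_statuses,
    score_segment_dyskinesia,
)
from onoff.signals import Segment, segment_recording
from onoff.synthetic import SimProfile, _snippet, simulate_recording


def _seg_from_snippet(cls, seed, profile=None):
    profile = profile or SimProfile()
    rng = np.random.default_rng(seed)
    data = _snippet(cls, profile, rng)
    return Segment(data=data, start_index=0, fs=profile.fs, minute_index=0, period_index=0)


def _status(gate, dysk="not_assessed", minute=0):
    return SegmentDyskStatus(minute_index=minute, gate=gate, dysk=dysk)


# --- gating -----------------------------------------------------------------


def test_gate_transition_simulant(config):
    hits = sum(
        gate_segment(_seg_from_snippet("transition", s), is_walking=False, config=config)
        == POSTURAL_TRANSITION
        for s in range(20)
    )
    assert hits >= 18


def test_gate_rest_is_analyzable(config):
    assert all(
        gate_segment(_seg_from_snippet("rest", s), is_walking=False, config=config) == ANALYZABLE
        for s in range(20)
    )


def test_gate_walking_takes_precedence(config):
    # even a segment loaded with low-band content is 'walking' if the SVM fired
    seg = _seg_from_snippet("transition", 0)
    assert gate_segment(seg, is_walking=True, config=config) == WALKING


# --- per-segment scoring ----------------------------------------------------


def test_choreic_simulant_scores_positive(config):
    hits = sum(
        score_segment_dyskinesia(_seg_from_snippet("dysk", s), config) == "positive"
        for s in range(20)
    )
    assert hits >= 18


def test_rest_scores_negative(config):
    assert all(
        score_segment_dyskinesia(_seg_from_snippet("rest", s), config) == "negative"
        for s in range(20)
    )


def test_zero_signal_scores_negative(config):
    seg = Segment(data=np.zeros((128, 3)), start_index=0, fs=40.0, minute_index=0, period_index=0)
    assert score_segment_dyskinesia(seg, config) == "negative"


# --- minute rule ------------------------------------------------------------


def test_minute_under_30_percent_analyzable_is_undetermined(config):
    sts = [_status(ANALYZABLE, "positive")] * 4 + [_status(WALKING)] * 14  # 4/18 = 22%
    assert aggregate_minute(sts, 0, config).status == UNDETERMINED


def test_minute_over_40_percent_positive_is_present(config):
    sts = [_status(ANALYZABLE, "positive")] * 5 + [_status(ANALYZABLE, "negative")] * 5
    sts += [_status(WALKING)] * 8  # 10/18 analyzable, 5/10 positive
    assert aggregate_minute(sts, 0, config).status == PRESENT


def test_minute_exactly_40_percent_positive_is_absent(config):
    """'higher than 40%' is strict: 4/10 positive stays absent."""
    sts = [_status(ANALYZABLE, "positive")] * 4 + [_status(ANALYZABLE, "negative")] * 6
    sts += [_status(POSTURAL_TRANSITION)] * 8
    assert aggregate_minute(sts, 0, config).status == ABSENT


def test_empty_minute_is_undetermined(config):
    assert aggregate_minute([], 0, config).status == UNDETERMINED


# --- period rule ------------------------------------------------------------


def _minutes(statuses):
    return [MinuteDyskStatus(i, s) for i, s in enumerate(statuses)]


@pytest.mark.parametrize(
    "statuses,expected",
    [
        ([UNDETERMINED] * 8 + [PRESENT] * 2, UNDETERMINED),
        ([UNDETERMINED] * 10, UNDETERMINED),
        ([UNDETERMINED] * 3 + [PRESENT] * 4 + [ABSENT] * 3, PRESENT),
        ([UNDETERMINED] * 2 + [PRESENT] * 4 + [ABSENT] * 4, ABSENT),  # tie -> absent
        ([UNDETERMINED] * 7 + [ABSENT] * 3, ABSENT),
        ([PRESENT] * 6 + [ABSENT] * 4, PRESENT),
    ],
)
def test_period_aggregation_rules(statuses, expected, config):
    assert aggregate_period(_minutes(statuses), 0, config).status == expected


def test_period_requires_exactly_ten_minutes(config):
    with pytest.raises(ValueError):
        aggregate_period(_minutes([ABSENT] * 9), 0, config)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([PRESENT, ABSENT, UNDETERMINED]), min_size=10, max_size=10),
       st.randoms(use_true_random=False))
def test_period_status_invariant_to_minute_permutation(statuses, rnd):
    base = aggregate_period(_minutes(statuses), 0).status
    shuffled = list(statuses)
    rnd.shuffle(shuffled)
    assert aggregate_period(_minutes(shuffled), 0).status == base


# --- end-to-end against the generator --------------------------------------


def test_choreic_rest_periods_flag_present(walk_model, config):
    """Periods with >= 50% choreic time at rest -> present in >= 90%."""
    profile = SimProfile(seed=21, day_hours=2.0, bout_rate_per_min=0.0,
                         pt_rate_per_hour=0.0, dysk_duty=0.65,
                         schedule=[(0.0, 7200.0, "On")])
    rec, _, _ = simulate_recording(profile)
    segs = segment_recording(rec, config.window_s)
    statuses = period_dysk_statuses(segs, walk_model, 12, config)
    present = sum(s.status == PRESENT for s in statuses)
    assert present >= 0.90 * len(statuses)


def test_quiet_rest_periods_flag_absent(walk_model, config):
    """Fully-at-rest, dyskinesia-free day -> absent in >= 95% of periods."""
    profile = SimProfile(seed=22, day_hours=2.0, bout_rate_per_min=0.0,
                         pt_rate_per_hour=0.0, dysk_amplitude=0.0,
                         schedule=[(0.0, 7200.0, "On")])
    rec, _, _ = simulate_recording(profile)
    segs = segment_recording(rec, config.window_s)
    statuses = period_dysk_statuses(segs, walk_model, 12, config)
    absent = sum(s.status == ABSENT for s in statuses)
    assert absent >= 0.95 * len(statuses)
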