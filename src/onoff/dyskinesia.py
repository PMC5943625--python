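"""Choreic dyskinesia detection outside walking and postural transitions.

Walking and postural transitions can hide dyskinetic movement, so each
3.2-s segment is first gated: walking (the SVM fires), else postural
transition (0.1-0.6 Hz band power above the global tau_pt), else
analyzable.  Analyzable segments are scored positive when their 1-4 Hz
band power exceeds the global tau_dysk.

Aggregation: a minute is undetermined when fewer than 30% of its segments
are analyzable; otherwise dyskinesia is present when more than 40% of the
analyzable segments score positive (both strict inequalities).  A 10-min
period is undetermined when at least 8 of its 10 minutes are
undetermined; otherwise the most frequent determined minute status wins,
with present/absent ties resolved to absent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .gait_svm import WalkModel, detect_walking
from .signals import Segment, band_power

WALKING = "walking"
POSTURAL_TRANSITION = "postural_transition"
ANALYZABLE = "analyzable"

PRESENT = "present"
ABSENT = "absent"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class SegmentDyskStatus:
    minute_index: int
    gate: str
    dysk: str  # 'positive' | 'negative' | 'not_assessed'


@dataclass(frozen=True)
class MinuteDyskStatus:
    minute_index: int
    status: str


@dataclass(frozen=True)
class PeriodDyskStatus:
    period_index: int
    status: str


def gate_segment(
    seg: Segment, is_walking: bool, config: PipelineConfig | None = None
) -> str:
    """Gate label: walking beats postural transition beats analyzable."""
    config = config or PipelineConfig()
    if is_walking:
        return WALKING
    lo, hi = config.pt_band
    if band_power(seg, lo, hi).value > config.tau_pt:
        return POSTURAL_TRANSITION
    return ANALYZABLE


def score_segment_dyskinesia(seg: Segment, config: PipelineConfig | None = None) -> str:
    """'positive' iff 1-4 Hz summed band power exceeds the global threshold."""
    config = config or PipelineConfig()
    lo, hi = config.dysk_band
    return "positive" if band_power(seg, lo, hi).value > config.tau_dysk else "negative"


def score_segments(
    segments: list[Segment],
    walk_model: WalkModel,
    config: PipelineConfig | None = None,
    walking: np.ndarray | None = None,
) -> list[SegmentDyskStatus]:
    """Gate and score every segment (walk flags computed once if absent)."""
    config = config or PipelineConfig()
    if walking is None:
        walking = detect_walking(walk_model, segments, config)
    out = []
    for seg, w in zip(segments, walking):
        gate = gate_segment(seg, bool(w), config)
        dysk = score_segment_dyskinesia(seg, config) if gate == ANALYZABLE else "not_assessed"
        out.append(SegmentDyskStatus(minute_index=seg.minute_index, gate=gate, dysk=dysk))
    return out


def aggregate_minute(
    statuses: list[SegmentDyskStatus],
    minute_index: int,
    config: PipelineConfig | None = None,
) -> MinuteDyskStatus:
    """Minute verdict from its segment statuses (empty minute => undetermined)."""
    config = config or PipelineConfig()
    if not statuses:
        return MinuteDyskStatus(minute_index, UNDETERMINED)
    n_all = len(statuses)
    analyzable = [s for s in statuses if s.gate == ANALYZABLE]
    if len(analyzable) / n_all < config.minute_min_analyzable_ratio:
        return MinuteDyskStatus(minute_index, UNDETERMINED)
    positives = sum(1 for s in analyzable if s.dysk == "positive")
    if positives / len(analyzable) > config.minute_positive_ratio:
        return MinuteDyskStatus(minute_index, PRESENT)
    return MinuteDyskStatus(minute_index, ABSENT)


def aggregate_period(
    minutes: list[MinuteDyskStatus],
    period_index: int,
    config: PipelineConfig | None = None,
) -> PeriodDyskStatus:
    """Period verdict from exactly 10 minute statuses."""
    config = config or PipelineConfig()
    if len(minutes) != 10:
        raise ValueError(f"a period needs exactly 10 minutes, got {len(minutes)}")
    counts = Counter(m.status for m in minutes)
    if counts[UNDETERMINED] >= config.period_undetermined_min:
        return PeriodDyskStatus(period_index, UNDETERMINED)
    if counts[PRESENT] > counts[ABSENT]:
        return PeriodDyskStatus(period_index, PRESENT)
    return PeriodDyskStatus(period_index, ABSENT)  # tie breaks toward absent


def period_dysk_statuses(
    segments: list[Segment],
    walk_model: WalkModel,
    n_periods: int,
    config: PipelineConfig | None = None,
    walking: np.ndarray | None = None,
) -> list[PeriodDyskStatus]:
    """Full dyskinesia chain: segments -> minutes -> 10-min periods."""
    config = config or PipelineConfig()
    seg_statuses = score_segments(segments, walk_model, config, walking=walking)
    by_minute: dict[int, list[SegmentDyskStatus]] = {}
    for s in seg_statuses:
        by_minute.setdefault(s.minute_index, []).append(s)
    out = []
    for p in range(n_periods):
        minutes = [
            aggregate_minute(by_minute.get(m, []), m, config)
            for m in range(10 * p, 10 * p + 10)
        ]
        out.append(aggregate_period(minutes, p, config))
    return out
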