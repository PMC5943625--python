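"""Fusion of gait and dyskinesia outputs into On / Off / Intermediate /
Unknown, plus the three-consecutive-period gap-filling rule.

Dyskinesia only occurs in the On-state, so detected dyskinesia forces On
regardless of gait.  Otherwise the gait verdict decides: normal gait =>
On, bradykinetic => Off, intermediate => Intermediate, and no assessable
movement at all => Unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import bradykinesia as bk
from . import dyskinesia as dk
from .config import PipelineConfig

ON = "On"
OFF = "Off"
INTERMEDIATE_STATE = "Intermediate"
UNKNOWN = "Unknown"

CONCLUSIVE = (ON, OFF)


@dataclass(frozen=True)
class PeriodOutput:
    period_index: int
    gait: str  # GaitPeriodStatus.status
    dysk: str  # PeriodDyskStatus.status
    state: str
    filled: bool = False


def fuse(gait: str, dysk: str) -> str:
    """Motor state of one period from its gait and dyskinesia verdicts.

    An undetermined dyskinesia verdict is treated as 'did not show
    dyskinesia' whenever gait is informative.
    """
    if gait not in (bk.BRADYKINETIC, bk.INTERMEDIATE, bk.NORMAL, bk.INDETERMINATE):
        raise ValueError(f"invalid gait status {gait!r}")
    if dysk not in (dk.PRESENT, dk.ABSENT, dk.UNDETERMINED):
        raise ValueError(f"invalid dyskinesia status {dysk!r}")
    if dysk == dk.PRESENT:
        return ON
    if gait == bk.NORMAL:
        return ON
    if gait == bk.BRADYKINETIC:
        return OFF
    if gait == bk.INTERMEDIATE:
        return INTERMEDIATE_STATE
    return UNKNOWN


def fuse_periods(
    gait_statuses: list[bk.GaitPeriodStatus], dysk_statuses: list[dk.PeriodDyskStatus]
) -> list[PeriodOutput]:
    if len(gait_statuses) != len(dysk_statuses):
        raise ValueError("gait and dyskinesia period lists must align")
    return [
        PeriodOutput(
            period_index=g.period_index,
            gait=g.status,
            dysk=d.status,
            state=fuse(g.status, d.status),
        )
        for g, d in zip(gait_statuses, dysk_statuses)
    ]


def fill_gaps(
    periods: list[PeriodOutput], config: PipelineConfig | None = None
) -> list[PeriodOutput]:
    """Fill single Unknown periods flanked by two equal known states.

    One left-to-right pass over consecutive triples (window stride from
    config; filled values may seed later triples when the stride is 1).
    Never alters a non-Unknown period.
    """
    config = config or PipelineConfig()
    out = list(periods)
    for i in range(0, len(out) - 2, config.triple_stride):
        a, b, c = out[i], out[i + 1], out[i + 2]
        if b.state == UNKNOWN and a.state == c.state and a.state != UNKNOWN:
            out[i + 1] = replace(b, state=a.state, filled=True)
    return out


def conclusive(periods: list[PeriodOutput]) -> list[PeriodOutput]:
    """Periods classified On or Off (the countable detections)."""
    return [p for p in periods if p.state in CONCLUSIVE]
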