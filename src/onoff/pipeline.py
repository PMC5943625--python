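"""End-to-end composition: recording -> per-period motor states.

Stages, in order: segmentation, walk detection (frozen SVM), walking
bouts, stride detection + fluidity, unsupervised patient threshold, gait
classification per 10-min period, dyskinesia gating/scoring/aggregation,
fusion, gap filling.  Deterministic given (recording, model, config).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import bradykinesia as bk
from . import dyskinesia as dk
from . import motor_state as ms
from .config import PipelineConfig
from .gait_svm import WalkModel, detect_walking, walking_bouts
from .signals import AccelRecording, segment_recording
from .stride import extract_strides

log = logging.getLogger("onoff")


def run_pipeline(
    rec: AccelRecording, model: WalkModel, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Classify every complete 10-min period of a recording.

    Returns one row per period: ``period_index, mean_fluidity, gait,
    dyskinesia, state, filled``.  Patients with too few strides for a
    threshold get all-indeterminate gait.
    """
    config = config or PipelineConfig()
    segments = segment_recording(rec, config.window_s)
    n_periods = int(rec.duration_s // 600.0)
    if n_periods == 0:
        raise ValueError("recording shorter than one 10-min period")
    segments = [s for s in segments if s.period_index < n_periods]
    log.info("stage=segment n_segments=%d n_periods=%d", len(segments), n_periods)

    walking = detect_walking(model, segments, config)
    bouts = walking_bouts(segments, walking)
    log.info("stage=walk n_walking=%d n_bouts=%d", int(walking.sum()), len(bouts))

    strides = extract_strides(rec, bouts, config)
    log.info("stage=stride n_strides=%d", len(strides))

    means = bk.period_mean_fluidity(strides)
    try:
        threshold = bk.estimate_threshold([s.fluidity for s in strides], config)
        log.info(
            "stage=threshold theta=%.3f method=%s", threshold.theta, threshold.method
        )
        gait = [
            bk.classify_gait(p, means.get(p), threshold, config) for p in range(n_periods)
        ]
    except bk.TooFewStrides:
        log.info("stage=threshold status=too-few-strides")
        threshold = None
        gait = [bk.GaitPeriodStatus(p, means.get(p), bk.INDETERMINATE) for p in range(n_periods)]

    dysk = dk.period_dysk_statuses(segments, model, n_periods, config, walking=walking)
    periods = ms.fill_gaps(ms.fuse_periods(gait, dysk), config)
    log.info(
        "stage=fuse conclusive=%d of=%d", len(ms.conclusive(periods)), len(periods)
    )

    return pd.DataFrame(
        {
            "period_index": [p.period_index for p in periods],
            "mean_fluidity": [
                None if g.mean_fluidity is None else g.mean_fluidity for g in gait
            ],
            "gait": [p.gait for p in periods],
            "dyskinesia": [p.dysk for p in periods],
            "state": [p.state for p in periods],
            "filled": [p.filled for p in periods],
        }
    )


def write_states_csv(
    df: pd.DataFrame, path: str | Path, config: PipelineConfig, patient_id: str
) -> None:
    """States table with a provenance header (config hash, patient)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# onoff states patient={patient_id} config_hash={config.config_hash()}\n")
        df.to_csv(fh, index=False, float_format="%.4f")


def states_to_periods(df: pd.DataFrame) -> list[ms.PeriodOutput]:
    return [
        ms.PeriodOutput(
            period_index=int(r.period_index),
            gait=r.gait,
            dysk=r.dyskinesia,
            state=r.state,
            filled=bool(r.filled),
        )
        for r in df.itertuples()
    ]
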