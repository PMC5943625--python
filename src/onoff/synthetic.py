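"""Synthetic accelerometry with known ground truth.

Emulates the signal classes a waist-worn sensor sees in a fluctuating
Parkinson's day, at the level of detail the detectors consume:

* gait bouts as harmonic stride trains — fundamental at the step cadence,
  with a state-dependent harmonic mix: fluent (On) strides concentrate
  power in the first two harmonics, bradykinetic (Off) strides are slower,
  smaller and spread power into the 3rd-5th harmonics;
* choreic dyskinesia as band-limited 1-4 Hz noise at rest during On;
* postural transitions (sit-to-stand) as 0.1-0.6 Hz half-sine transients;
* rest as low-amplitude white noise, plus a constant gravity offset on
  the vertical channel;
* an imperfect self-report diary on a 30-min grid.

The event log records every bout, step time, dyskinetic interval and
transition, so each pipeline stage can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signals import AccelRecording, Segment

# harmonic mixes: state -> list of (channel, harmonic k, relative amplitude)
# channel 2 is vertical (carries gravity); minima coincide at step contacts.
ON_MIX = [(2, 1, 1.0), (2, 2, 0.3), (0, 1, 0.4), (1, 1, 0.5), (1, 2, 0.2)]
OFF_MIX = [
    (2, 1, 0.55), (2, 3, 0.6), (2, 4, 0.5), (2, 5, 0.35),
    (0, 1, 0.25), (0, 3, 0.3), (1, 1, 0.3), (1, 4, 0.3),
]
GRAVITY = 9.81


@dataclass
class SimProfile:
    """Generator settings; defaults are the reference study conditions."""

    seed: int = 0
    day_hours: float = 8.0
    fs: float = 40.0
    # piecewise-constant ground truth; None -> alternating Off/On blocks
    schedule: list[tuple[float, float, str]] | None = None  # (start_s, end_s, state)
    block_minutes: float = 60.0
    # gait
    bout_rate_per_min: float = 0.3
    bout_duration_s: tuple[float, float] = (20.0, 45.0)
    cadence_on: float = 1.8  # steps/s
    cadence_off: float = 1.2
    fluidity_on: tuple[float, float] = (10.0, 0.5)  # target mean, SD (m/s^2)
    fluidity_off: tuple[float, float] = (2.5, 0.4)
    # dyskinesia (during On, at rest)
    dysk_amplitude: float = 1.5  # total RMS across channels, m/s^2
    dysk_duty: float = 0.5
    dysk_tile_s: float = 30.0
    # postural transitions
    pt_rate_per_hour: float = 10.0
    pt_amplitude: float = 2.0
    pt_duration_s: tuple[float, float] = (2.5, 5.0)
    # sensor
    noise_sd: float = 0.08
    # diary
    diary_compliance: float = 0.9
    diary_error: float = 0.05

    def resolved_schedule(self) -> list[tuple[float, float, str]]:
        if self.schedule is not None:
            return list(self.schedule)
        day_s = self.day_hours * 3600.0
        block = self.block_minutes * 60.0
        out, t, state = [], 0.0, "Off"
        while t < day_s - 1e-9:
            end = min(t + block, day_s)
            out.append((t, end, state))
            state = "On" if state == "Off" else "Off"
            t = end
        return out


def _mix_for(state: str):
    return ON_MIX if state == "On" else OFF_MIX


def _amplitude_for_fluidity(mix, target: float) -> float:
    """Base amplitude giving the requested ideal fluidity value.

    Fluidity = sqrt(power in harmonics 1-2 / total power) * RMS; for a
    pure harmonic train both terms are closed-form in the mix amplitudes.
    """
    s_all = sum(a * a for _, _, a in mix) / 2.0
    s_12 = sum(a * a for _, k, a in mix if k <= 2) / 2.0
    ratio = s_12 / s_all
    return target / (np.sqrt(ratio) * np.sqrt(s_all))


def _render_bout(
    x: np.ndarray, fs: float, t0: float, t1: float, state: str, fluidity: float, cadence: float
) -> np.ndarray:
    """Add one stride train to the signal; returns the step contact times."""
    mix = _mix_for(state)
    amp = _amplitude_for_fluidity(mix, fluidity)
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    t = np.arange(i0, i1) / fs
    c0 = t0 + 0.5 / cadence  # first contact
    base = 2.0 * np.pi * cadence * (t - c0)
    for ch, k, a in mix:
        x[i0:i1, ch] -= amp * a * np.cos(k * base)
    contacts = np.arange(c0, t1 - 0.25 / cadence, 1.0 / cadence)
    return contacts


def _bandlimited_noise(n: int, fs: float, lo: float, hi: float, rng) -> np.ndarray:
    w = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, w)
    sd = y.std()
    return y / sd if sd > 0 else y


def _half_sine(n: int) -> np.ndarray:
    return np.sin(np.pi * np.arange(n) / max(n - 1, 1))


def simulate_recording(
    profile: SimProfile, patient_id: str = "sim"
) -> tuple[AccelRecording, pd.DataFrame, dict]:
    """Render one day; returns (recording, per-period truth, event log).

    The truth table has one row per complete 10-min period with the
    majority ground-truth state.  The event log dict carries ``bouts``,
    ``steps`` (contact times, s), ``dysk_intervals`` and ``transitions``.
    """
    rng = np.random.default_rng(profile.seed)
    fs = profile.fs
    day_s = profile.day_hours * 3600.0
    n = int(round(day_s * fs))
    x = np.zeros((n, 3))
    schedule = profile.resolved_schedule()

    # --- gait bouts ----------------------------------------------------
    bouts, all_steps = [], []
    for b0, b1, state in schedule:
        if state not in ("On", "Off", "Intermediate") or profile.bout_rate_per_min <= 0:
            continue
        t = b0 + float(rng.exponential(60.0 / profile.bout_rate_per_min))
        while t < b1 - profile.bout_duration_s[0]:
            dur = float(rng.uniform(*profile.bout_duration_s))
            end = min(t + dur, b1)
            if state == "Intermediate":
                flu = float(
                    rng.normal(
                        0.5 * (profile.fluidity_on[0] + profile.fluidity_off[0]),
                        profile.fluidity_on[1],
                    )
                )
                cad, st = 0.5 * (profile.cadence_on + profile.cadence_off), "On"
            elif state == "On":
                flu = float(rng.normal(*profile.fluidity_on))
                cad, st = profile.cadence_on, "On"
            else:
                flu = float(rng.normal(*profile.fluidity_off))
                cad, st = profile.cadence_off, "Off"
            flu = max(flu, 0.3)
            contacts = _render_bout(x, fs, t, end, st, flu, cad)
            bouts.append((t, end, state, cad, flu, len(contacts)))
            all_steps.extend(contacts.tolist())
            t = end + float(rng.exponential(60.0 / profile.bout_rate_per_min)) + 5.0

    in_bout = np.zeros(n, dtype=bool)
    for b0, b1, *_ in bouts:
        in_bout[int(b0 * fs) : int(b1 * fs)] = True

    # --- dyskinesia: 1-4 Hz noise at rest during On --------------------
    dysk_intervals = []
    if profile.dysk_amplitude > 0 and profile.dysk_duty > 0:
        per_ch = profile.dysk_amplitude / np.sqrt(3.0)
        noise = np.stack(
            [_bandlimited_noise(n, fs, 1.0, 4.0, rng) * per_ch for _ in range(3)], axis=1
        )
        for b0, b1, state in schedule:
            if state != "On":
                continue
            t = b0
            while t < b1:
                end = min(t + profile.dysk_tile_s, b1)
                if rng.random() < profile.dysk_duty:
                    i0, i1 = int(t * fs), int(end * fs)
                    mask = ~in_bout[i0:i1]
                    x[i0:i1][mask] += noise[i0:i1][mask]
                    if mask.any():
                        dysk_intervals.append((t, end))
                t = end

    # --- postural transitions at rest ----------------------------------
    transitions = []
    n_pt = rng.poisson(profile.pt_rate_per_hour * profile.day_hours)
    for _ in range(n_pt):
        dur = float(rng.uniform(*profile.pt_duration_s))
        for _attempt in range(20):
            t0 = float(rng.uniform(0.0, day_s - dur))
            i0, i1 = int(t0 * fs), int((t0 + dur) * fs)
            if not in_bout[i0:i1].any():
                bump = profile.pt_amplitude * _half_sine(i1 - i0)
                x[i0:i1, 2] += bump
                x[i0:i1, 0] += 0.4 * bump
                transitions.append((t0, t0 + dur))
                break

    # --- sensor noise + gravity ---------------------------------------
    x += rng.normal(0.0, profile.noise_sd, size=x.shape)
    x[:, 2] += GRAVITY

    rec = AccelRecording(patient_id=patient_id, fs=fs, samples=x)

    n_periods = int(day_s // 600)
    rows = []
    for p in range(n_periods):
        p0, p1 = p * 600.0, (p + 1) * 600.0
        tally: dict[str, float] = {}
        for b0, b1, state in schedule:
            ov = max(0.0, min(b1, p1) - max(b0, p0))
            if ov > 0:
                tally[state] = tally.get(state, 0.0) + ov
        rows.append({"period_index": p, "state": max(tally, key=tally.get)})
    truth = pd.DataFrame(rows)

    events = {
        "bouts": pd.DataFrame(
            bouts, columns=["start_s", "end_s", "state", "cadence", "fluidity", "n_steps"]
        ),
        "steps": np.array(sorted(all_steps)),
        "dysk_intervals": pd.DataFrame(dysk_intervals, columns=["start_s", "end_s"]),
        "transitions": pd.DataFrame(transitions, columns=["start_s", "end_s"]),
        "schedule": schedule,
    }
    return rec, truth, events


def simulate_diary(
    schedule: list[tuple[float, float, str]],
    day_s: float,
    compliance: float,
    error_rate: float,
    seed: int,
) -> pd.DataFrame:
    """Self-reports on a 30-min grid: majority state, flipped with the
    error rate, omitted with probability 1 - compliance."""
    rng = np.random.default_rng(seed)
    rows = []
    n_slots = int(day_s // 1800)
    for s in range(n_slots):
        s0, s1 = s * 1800.0, (s + 1) * 1800.0
        tally = {"On": 0.0, "Off": 0.0}
        for b0, b1, state in schedule:
            if state in tally:
                tally[state] += max(0.0, min(b1, s1) - max(b0, s0))
        if tally["On"] == 0.0 and tally["Off"] == 0.0:
            continue
        state = "On" if tally["On"] >= tally["Off"] else "Off"
        if rng.random() >= compliance:
            continue
        if rng.random() < error_rate:
            state = "Off" if state == "On" else "On"
        rows.append({"slot_index": s, "state": state})
    return pd.DataFrame(rows, columns=["slot_index", "state"])


# ---------------------------------------------------------------------------
# labelled 3.2-s snippet corpus (walk-classifier training, threshold calibration)


def _snippet(cls: str, profile: SimProfile, rng) -> np.ndarray:
    fs = profile.fs
    n = int(fs * 3.2)
    x = np.zeros((n, 3))
    if cls == "walk":
        if rng.random() < 0.5:
            flu, cad, st = float(rng.normal(*profile.fluidity_on)), profile.cadence_on, "On"
        else:
            flu, cad, st = float(rng.normal(*profile.fluidity_off)), profile.cadence_off, "Off"
        long = np.zeros((int(fs * 8.0), 3))
        _render_bout(long, fs, 0.0, 8.0, st, max(flu, 0.3), cad)
        off = rng.integers(0, long.shape[0] - n)
        x = long[off : off + n].copy()
    elif cls == "dysk":
        per_ch = profile.dysk_amplitude / np.sqrt(3.0)
        x = np.stack(
            [_bandlimited_noise(n, fs, 1.0, 4.0, rng) * per_ch for _ in range(3)], axis=1
        )
    elif cls == "transition":
        dur = int(float(rng.uniform(*profile.pt_duration_s)) * fs)
        bump = profile.pt_amplitude * _half_sine(dur)
        i0 = int(rng.integers(0, max(n - dur, 1)))
        seg = bump[: n - i0]
        x[i0 : i0 + len(seg), 2] += seg
        x[i0 : i0 + len(seg), 0] += 0.4 * seg
    elif cls != "rest":
        raise ValueError(f"unknown class {cls!r}")
    x += rng.normal(0.0, profile.noise_sd, size=x.shape)
    x[:, 2] += GRAVITY
    return x


def segment_corpus(
    profile: SimProfile, n_total: int, seed: int
) -> tuple[list[Segment], np.ndarray, np.ndarray]:
    """Balanced labelled corpus of walk / rest / dysk / transition segments.

    Returns (segments, class labels, is_walking booleans).
    """
    rng = np.random.default_rng(seed)
    classes = ["walk", "rest", "dysk", "transition"]
    per = n_total // len(classes)
    segs, labels = [], []
    for cls in classes:
        for _ in range(per):
            data = _snippet(cls, profile, rng)
            segs.append(
                Segment(data=data, start_index=0, fs=profile.fs, minute_index=0, period_index=0)
            )
            labels.append(cls)
    labels_arr = np.array(labels)
    return segs, labels_arr, labels_arr == "walk"


def calibrate_band_thresholds(
    profile: SimProfile, n_total: int = 800, seed: int = 20220414
) -> tuple[float, float]:
    """One-off calibration of the global band-power thresholds.

    tau_pt separates postural transitions from other non-walking activity
    on 0.1-0.6 Hz power; tau_dysk separates choreic movement from rest on
    1-4 Hz power.  Each is the Youden-J-optimal cut on the corpus.
    """
    from .signals import band_power

    segs, labels, _ = segment_corpus(profile, n_total, seed)

    def youden_cut(pos_vals, neg_vals):
        vals = np.sort(np.unique(np.concatenate([pos_vals, neg_vals])))
        cuts = (vals[1:] + vals[:-1]) / 2.0
        best_j, best_c = -np.inf, cuts[0]
        for c in cuts:
            j = (pos_vals > c).mean() - (neg_vals > c).mean()
            if j > best_j:
                best_j, best_c = j, c
        return float(best_c)

    pt_pow = np.array([band_power(s, 0.1, 0.6).value for s in segs])
    dysk_pow = np.array([band_power(s, 1.0, 4.0).value for s in segs])
    tau_pt = youden_cut(pt_pow[labels == "transition"], pt_pow[np.isin(labels, ["rest", "dysk"])])
    tau_dysk = youden_cut(dysk_pow[labels == "dysk"], dysk_pow[labels == "rest"])
    return tau_pt, tau_dysk
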