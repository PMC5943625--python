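"""Segmentation, band power and spectral features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from onoff.config import PipelineConfig
from onoff.signals import (
    AccelRecording,
    Segment,
    band_power,
    band_power_array,
    feature_matrix,
    feature_vector,
    read_accel_csv,
    segment_recording,
    write_accel_csv,
)


def _rec(n, fs=40.0, data=None, seed=0):
    rng = np.random.default_rng(seed)
    x = data if data is not None else rng.standard_normal((n, 3))
    return AccelRecording(patient_id="t", fs=fs, samples=x)


def _seg(x, fs=40.0):
    return Segment(data=np.asarray(x, float), start_index=0, fs=fs, minute_index=0, period_index=0)


@pytest.mark.parametrize(
    "n_samples,expected_segments", [(1280, 10), (130, 1), (127, 0), (128, 1), (256, 2)]
)
def test_segmentation_counts(n_samples, expected_segments):
    segs = segment_recording(_rec(n_samples))
    assert len(segs) == expected_segments
    assert all(s.length == 128 for s in segs)


def test_segmentation_is_a_partition():
    rec = _rec(1280 + 37)
    segs = segment_recording(rec)
    starts = [s.start_index for s in segs]
    assert starts == [128 * i for i in range(10)]  # tiling, trailing 37 discarded
    covered = sum(s.length for s in segs)
    assert covered == 1280


def test_segment_minute_and_period_indices():
    rec = _rec(40 * 660)  # 11 minutes
    segs = segment_recording(rec)
    assert segs[0].minute_index == 0 and segs[0].period_index == 0
    late = [s for s in segs if s.start_s >= 600]
    assert all(s.period_index == 1 for s in late)
    assert {s.minute_index for s in segs} == set(range(11))


def test_fs_must_be_positive():
    with pytest.raises(ValueError):
        AccelRecording(patient_id="t", fs=0.0, samples=np.zeros((10, 3)))


def test_band_power_sinusoid_parseval():
    """A 2 Hz tone lands in the 1-4 Hz band with ~all of the AC power A^2/2."""
    fs, A = 40.0, 2.5
    t = np.arange(128) / fs
    x = np.zeros((128, 3))
    x[:, 0] = A * np.sin(2 * np.pi * 2.0 * t)
    seg = _seg(x)
    total_ac = np.var(x[:, 0])
    assert band_power(seg, 1.0, 4.0).value >= 0.95 * total_ac
    assert band_power(seg, 5.0, 10.0).value <= 0.02 * total_ac
    assert total_ac == pytest.approx(A * A / 2, rel=0.05)


def test_band_power_constant_signal_is_zero():
    seg = _seg(np.full((128, 3), 7.3))
    assert band_power(seg, 0.0, 20.0).value == 0.0


def test_band_power_partition_matches_time_domain_variance():
    """Parseval: band powers over a spectrum partition sum to the variance."""
    rng = np.random.default_rng(42)
    x = rng.standard_normal((128, 3))
    seg = _seg(x)
    edges = [0.0, 2.0, 5.0, 11.0, 20.0 + 1e-9]
    total = sum(band_power(seg, lo, hi).value for lo, hi in zip(edges[:-1], edges[1:]))
    var = np.var(x - x.mean(axis=0), axis=0).sum()
    assert total == pytest.approx(var, rel=0.01)


def test_band_power_rejects_degenerate_band():
    seg = _seg(np.zeros((128, 3)))
    with pytest.raises(ValueError):
        band_power(seg, 4.0, 4.0)
    with pytest.raises(ValueError):
        band_power(seg, 5.0, 30.0)  # beyond Nyquist


def test_band_power_offset_invariance():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((128, 3))
    a = band_power_array(x, 40.0, 1.0, 4.0).value
    b = band_power_array(x + np.array([9.81, -3.0, 100.0]), 40.0, 1.0, 4.0).value
    assert a == pytest.approx(b, rel=1e-9)


def test_feature_vector_deterministic_and_offset_invariant(config):
    rng = np.random.default_rng(2)
    x = rng.standard_normal((128, 3))
    v1 = feature_vector(_seg(x), config.featbank)
    v2 = feature_vector(_seg(x.copy()), config.featbank)
    np.testing.assert_array_equal(v1, v2)
    shifted = x.copy()
    shifted[:, 1] += 9.81
    v3 = feature_vector(_seg(shifted), config.featbank)
    np.testing.assert_allclose(v1, v3, rtol=1e-8)
    assert v1.shape == (4 * (len(config.featbank) - 1),)


def test_walk_vs_rest_features_linearly_separable(config, corpus):
    """Walking and rest spectra must be separable by a linear classifier."""
    segs, labels, _, X = corpus
    mask = np.isin(labels, ["walk", "rest"])
    clf = LogisticRegression(max_iter=2000).fit(X[mask], labels[mask] == "walk")
    assert clf.score(X[mask], labels[mask] == "walk") >= 0.95


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=2000))
def test_segmentation_count_formula(n):
    assert len(segment_recording(_rec(max(n, 1)))) == n // 128


def test_accel_csv_roundtrip(tmp_path):
    rec = _rec(400)
    path = tmp_path / "a.csv"
    write_accel_csv(rec, path)
    back = read_accel_csv(path, fs_expected=40.0)
    assert back.fs == pytest.approx(40.0, rel=0.01)
    np.testing.assert_allclose(back.samples, rec.samples, atol=1e-5)


def test_accel_csv_rejects_nonuniform_time(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("time_s,ax,ay,az\n0.0,0,0,0\n0.025,0,0,0\n0.30,0,0,0\n")
    with pytest.raises(ValueError, match="uniform"):
        read_accel_csv(path)
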