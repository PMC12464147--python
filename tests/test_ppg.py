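"""Pulse-wave extraction: construction oracles, invariances, QC rules."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nocturne as nt
from nocturne.ppg import (REJECT_PPT_RANGE, BeatMeasurement, ExtractionConfig,
                          locate_peaks)


def valid_ppts(beats):
    return np.array([b.ppt for b in beats if b.qc_status == "valid"])


# --------------------------------------------------------------------------
# beat detection
# --------------------------------------------------------------------------

def test_clean_minute_yields_one_window_per_beat(clean_night_factory):
    record, truth, _ = clean_night_factory(160.0, hours=1 / 60,
                                           heart_rate_bpm=60.0,
                                           heart_rate_sd=0.0,
                                           hrv_interval_sd=0.0)
    windows = nt.detect_beats(record)
    assert 57 <= len(windows) <= 60


def test_constant_signal_yields_no_windows():
    rec = nt.PPGRecord(sampling_rate=100.0, samples=np.full(6000, 1.7),
                       start_time=None, validity_mask=np.ones(6000, bool))
    assert nt.detect_beats(rec) == []


def test_windows_avoid_masked_samples(clean_night_factory):
    record, _, _ = clean_night_factory(160.0, hours=0.05)
    n = len(record.samples)
    record.validity_mask[n // 3: 2 * n // 3] = False
    for a, b in nt.detect_beats(record):
        assert record.validity_mask[a:b].all()


# --------------------------------------------------------------------------
# peak location
# --------------------------------------------------------------------------

@pytest.mark.parametrize("ppt", [120.0, 160.0, 200.0, 280.0])
def test_constant_ppt_recovered_with_subsample_precision(clean_night_factory, ppt):
    record, truth, _ = clean_night_factory(ppt)
    beats = nt.qc_beats(nt.measure_beats(record))
    ppts = valid_ppts(beats)
    assert len(ppts) > 100
    assert abs(ppts.mean() - ppt) <= 2.0       # well under one 10 ms sample


def test_single_bump_never_fabricates_distinct_peak():
    # beats with no reflected wave at all
    fs, n = 100.0, 3000
    t = np.arange(n) / fs
    x = np.zeros(n)
    for foot in np.arange(0.25, n / fs - 1.2, 1.0):
        x += np.exp(-0.5 * ((t - foot - 0.18) / 0.03) ** 2)
    rec = nt.PPGRecord(sampling_rate=fs, samples=x, start_time=None,
                       validity_mask=np.ones(n, bool))
    beats = nt.measure_beats(rec)
    assert len(beats) > 10
    assert all(b.p2_kind != "distinct_peak" for b in beats)


def test_equal_prominence_tie_breaks_to_earlier_candidate():
    # palindromic search window -> two exactly equal-prominence peaks
    seg = np.array([0, 5, 4, 3, 2, 1, 0, 1, 2, 3, 2, 1, 0,
                    1, 2, 3, 2, 1, 0, 0], dtype=float)
    p1, p2, kind = locate_peaks(seg, sampling_rate=10.0, presmoothed=True)
    assert kind == "distinct_peak"
    assert p2 * 10.0 == pytest.approx(9.0, abs=1e-9)   # the earlier of 9 / 15


def test_amplitude_invariance(clean_night_factory):
    record, _, _ = clean_night_factory(200.0, hours=0.05)
    scaled = nt.PPGRecord(sampling_rate=record.sampling_rate,
                          samples=record.samples * 37.5,
                          start_time=record.start_time,
                          validity_mask=record.validity_mask)
    b1 = nt.measure_beats(record)
    b2 = nt.measure_beats(scaled)
    assert len(b1) == len(b2)
    for x, y in zip(b1, b2):
        assert x.p1_time == pytest.approx(y.p1_time, abs=1e-9)
        assert x.ppt == pytest.approx(y.ppt, abs=1e-9)


def test_oppt_scales_with_true_ppt_and_osi_inversely(clean_night_factory):
    rec_a, _, _ = clean_night_factory(140.0)
    rec_b, _, _ = clean_night_factory(210.0)
    cfg = ExtractionConfig(min_valid_hours=0.05)
    sa = nt.average_oppt(nt.qc_beats(nt.measure_beats(rec_a)), config=cfg)
    sb = nt.average_oppt(nt.qc_beats(nt.measure_beats(rec_b)), config=cfg)
    assert sb.oppt / sa.oppt == pytest.approx(1.5, rel=0.02)
    osi_a = nt.compute_osi(175.0, sa.oppt)
    osi_b = nt.compute_osi(175.0, sb.oppt)
    assert osi_a / osi_b == pytest.approx(1.5, rel=0.02)


# --------------------------------------------------------------------------
# quality control
# --------------------------------------------------------------------------

def _beat(ppt, foot=0.0, length=1.0, amp=1.0):
    return BeatMeasurement(foot_time=foot, p1_time=foot + 0.18,
                           p2_time=foot + 0.18 + ppt / 1000.0,
                           p2_kind="distinct_peak", ppt=ppt,
                           beat_len=length, amplitude=amp)


def test_qc_static_rules_and_idempotence():
    beats = [_beat(160.0, foot=i * 1.0) for i in range(20)]
    beats.append(_beat(450.0, foot=20.0))
    beats.append(_beat(160.0, foot=21.0, length=2.0))
    once = nt.qc_beats(beats)
    assert [b.qc_status for b in once[:20]] == ["valid"] * 20
    assert once[20].rejection_reason == REJECT_PPT_RANGE
    assert once[21].rejection_reason == "beat_length_out_of_range"
    twice = nt.qc_beats(once)
    assert [(b.qc_status, b.rejection_reason) for b in twice] \
        == [(b.qc_status, b.rejection_reason) for b in once]


def test_qc_identical_beats_all_valid():
    beats = nt.qc_beats([_beat(160.0, foot=i * 1.0) for i in range(50)])
    assert all(b.qc_status == "valid" for b in beats)


def test_qc_removes_artifact_beats_keeps_clean_ones(subject):
    profile, truth = subject
    cfg = nt.SimConfig(seed=21, night_hours=1.0, artifact_fraction=0.10,
                       mask_artifacts=False)
    record = nt.simulate_ppg_night(profile, truth, cfg)
    beats = nt.qc_beats(nt.measure_beats(record))
    spans = truth.night.artifact_spans

    def in_artifact(b):
        return any(a < b.foot_time + b.beat_len and b.foot_time < bb
                   for a, bb in spans)

    clean = [b for b in beats if not in_artifact(b)]
    dirty = [b for b in beats if in_artifact(b)]
    assert len(dirty) > 0
    kept_clean = np.mean([b.qc_status == "valid" for b in clean])
    removed_dirty = np.mean([b.qc_status == "rejected" for b in dirty])
    assert kept_clean >= 0.95
    assert removed_dirty >= 0.90


# --------------------------------------------------------------------------
# overnight averaging, OSI
# --------------------------------------------------------------------------

def test_average_oppt_is_plain_mean_with_validity_floor():
    five_hours = [_beat(150.0 if i % 2 else 170.0, foot=i * 1.0)
                  for i in range(18000)]
    s = nt.average_oppt(nt.qc_beats(five_hours))
    assert s.oppt == pytest.approx(160.0, abs=1e-9)
    assert s.valid_hours == pytest.approx(5.0, abs=0.01)

    two_hours = [_beat(160.0, foot=i * 1.0) for i in range(7200)]
    with pytest.raises(nt.InsufficientValidSignal) as err:
        nt.average_oppt(nt.qc_beats(two_hours))
    assert err.value.valid_hours == pytest.approx(2.0, abs=0.01)


def test_osi_hand_arithmetic():
    assert nt.compute_osi(175.3, 160.8) == pytest.approx(10.90, abs=0.005)
    assert nt.compute_osi(160.0, 160.0) == pytest.approx(10.0, abs=1e-12)
    with pytest.raises(ValueError):
        nt.compute_osi(175.0, 0.0)
    with pytest.raises(ValueError):
        nt.compute_osi(0.0, 160.0)


@settings(deadline=None, max_examples=100)
@given(height=st.floats(140.0, 210.0), oppt=st.floats(100.0, 400.0))
def test_osi_oppt_identity(height, oppt):
    osi = nt.compute_osi(height, oppt)
    assert osi * (oppt / 1000.0) == pytest.approx(height / 100.0, rel=1e-12)


@pytest.mark.parametrize("osi,expected", [
    (10.89, "low"), (10.9, "high"), (12.0, "high"),
])
def test_osi_group_boundary(osi, expected):
    assert nt.classify_osi_group(osi) == expected
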