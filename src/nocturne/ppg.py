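"""Beat-by-beat pulse propagation time (PPT) from overnight PPG.

The measurand is the delay between the first (systolic) and second
(reflected) peaks of each pulse wave.  Averaged over the whole valid
recording this gives the overnight pulse propagation time (OPPT, ms);
the overnight stiffness index is OSI = body height (m) / OPPT (s).

Processing order: band-pass foot detection -> per-beat peak location
with sub-sample parabolic refinement -> rolling quality control ->
overnight averaging with a > 3 h validity floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InsufficientValidSignal
from .synth import PPGRecord

log = logging.getLogger(__name__)

REJECT_PPT_RANGE = "ppt_out_of_range"
REJECT_BEAT_LEN = "beat_length_out_of_range"
REJECT_UPSTROKE = "implausible_upstroke_time"
REJECT_AMP = "amplitude_outlier"
REJECT_PPT_DEV = "ppt_deviates_from_rolling_median"
REJECT_NO_P2 = "no_second_peak"


@dataclass
class ExtractionConfig:
    """Tunables of the beat detector and peak locator."""

    band_hz: Tuple[float, float] = (0.5, 8.0)   # foot-detection band-pass
    smooth_hz: float = 12.0                     # zero-phase low-pass for peaks
    min_beat_s: float = 0.4
    max_beat_s: float = 1.5
    p2_margin_s: float = 0.08                   # search window margins around p1/end
    p2_min_prominence_frac: float = 0.01        # of the segment's amplitude range
    foot_prominence_frac: float = 0.25          # of the filtered signal SD
    averaging: str = "mean"                     # "mean" or "median"
    min_valid_hours: float = 3.0


@dataclass
class QCRules:
    ppt_window_ms: Tuple[float, float] = (100.0, 400.0)
    beat_len_s: Tuple[float, float] = (0.4, 1.5)
    upstroke_s: Tuple[float, float] = (0.08, 0.35)   # foot -> systolic peak
    amp_z_max: float = 3.0
    amp_scale_floor_frac: float = 0.05   # robust-scale floor, fraction of median
    rolling_window_s: float = 300.0
    ppt_dev_ms: float = 80.0


@dataclass
class BeatMeasurement:
    foot_time: float                 # s from record start
    p1_time: float                   # s, systolic peak
    p2_time: Optional[float]         # s, reflected peak (None if not found)
    p2_kind: Optional[str]           # "distinct_peak" | "inflection"
    ppt: Optional[float]             # ms
    beat_len: float                  # s
    amplitude: float                 # p1 height above foot
    qc_status: str = "valid"
    rejection_reason: Optional[str] = None


@dataclass
class OvernightSummary:
    oppt: float                      # ms
    osi: Optional[float]             # m/s (None until height applied)
    n_beats_total: int
    n_beats_valid: int
    valid_hours: float
    osi_group: Optional[str] = None  # "low" | "high"


# --------------------------------------------------------------------------
# beat segmentation
# --------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float, band: Tuple[float, float]) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(band[1], 0.95 * nyq)
    sos = signal.butter(2, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    nyq = fs / 2.0
    sos = signal.butter(2, min(cutoff, 0.95 * nyq) / nyq, btype="low", output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_beats(record: PPGRecord,
                 config: Optional[ExtractionConfig] = None) -> List[Tuple[int, int]]:
    """Locate beat windows as half-open sample ranges ``[foot_i, foot_{i+1})``.

    Feet are local minima of the band-passed signal separated by a
    physiological interval; windows overlapping masked (artifact) samples
    are dropped.  A flat or garbage record yields an empty list.
    """
    cfg = config or ExtractionConfig()
    fs = record.sampling_rate
    x = record.samples
    if len(x) < int(10 * fs):
        log.warning("record shorter than 10 s; no beats detected")
        return []
    filt = _bandpass(x, fs, cfg.band_hz)
    sd = float(filt.std())
    if sd <= 0 or not np.isfinite(sd):
        log.warning("flat signal; no beats detected")
        return []
    # systolic peaks first (distance keeps the taller of close peaks, so
    # reflected peaks are suppressed), then the foot = minimum of the
    # upstroke window just before each systolic peak
    sys_peaks, _ = signal.find_peaks(filt, distance=max(1, int(cfg.min_beat_s * fs)),
                                     prominence=cfg.foot_prominence_frac * sd)
    if len(sys_peaks) < 2:
        log.warning("no beats found in record")
        return []
    up_win = max(2, int(0.35 * fs))
    feet = np.array(sorted({int(p - up_win + np.argmin(filt[max(0, p - up_win):p + 1]))
                            for p in sys_peaks if p - up_win >= 0}))
    if len(feet) < 2:
        log.warning("no beats found in record")
        return []

    bad = ~record.validity_mask
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    windows = []
    for a, b in zip(feet[:-1], feet[1:]):
        length = (b - a) / fs
        if not (cfg.min_beat_s <= length <= cfg.max_beat_s):
            continue
        if bad_cum[b] - bad_cum[a] > 0:    # overlaps masked samples
            continue
        windows.append((int(a), int(b)))
    return windows


# --------------------------------------------------------------------------
# per-beat peak location
# --------------------------------------------------------------------------

def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample vertex of the parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(i) + float(np.clip(delta, -0.5, 0.5))


def locate_peaks(window: np.ndarray, sampling_rate: float,
                 config: Optional[ExtractionConfig] = None,
                 presmoothed: bool = False):
    """Find the systolic peak p1 and the reflected peak p2 in one beat.

    p1 is the global maximum of the smoothed segment.  p2 is searched in
    ``(p1 + margin, end - margin]``: the most prominent local maximum if
    one exists (ties broken toward the earlier candidate — the reflected
    wave is the physiologically earlier event), otherwise the local
    maximum of the first derivative on the decaying limb (shoulder /
    inflection fallback).  Both are refined to sub-sample precision by
    three-point parabolic interpolation.

    Returns ``(p1_time, p2_time, p2_kind)`` in seconds from window start,
    with ``p2_time``/``p2_kind`` None when no admissible candidate exists.
    """
    cfg = config or ExtractionConfig()
    fs = sampling_rate
    seg = np.asarray(window, dtype=float)
    s = seg if presmoothed else _lowpass(seg, fs, cfg.smooth_hz)

    i1 = int(np.argmax(s))
    p1_time = _parabolic_refine(s, i1) / fs

    margin = int(round(cfg.p2_margin_s * fs))
    lo = i1 + margin + 1
    hi = len(s) - margin            # exclusive
    if hi - lo < 3:
        return p1_time, None, None

    sub = s[lo - 1:hi + 1]          # pad one sample for edge maxima context
    min_prom = cfg.p2_min_prominence_frac * float(np.ptp(s))
    peaks, props = signal.find_peaks(sub, prominence=min_prom)
    peaks = peaks[(peaks >= 1) & (peaks <= hi - lo)]
    if len(peaks):
        prom = signal.peak_prominences(sub, peaks)[0]
        best = peaks[int(np.argmax(prom))]       # argmax -> earliest on ties
        i2 = lo - 1 + int(best)
        p2_time = _parabolic_refine(s, i2) / fs
        return p1_time, p2_time, "distinct_peak"

    # fallback: shoulder of the decay limb = interior local maximum of the
    # first derivative, restricted to where the pulse still has amplitude
    # (>= 25 % of the systolic rise above the segment floor) so flat-tail
    # plateaus are never mistaken for a reflected wave
    d = np.gradient(s)
    dsub = d[lo:hi]
    if len(dsub) < 3:
        return p1_time, None, None
    interior = (dsub[1:-1] > dsub[:-2]) & (dsub[1:-1] >= dsub[2:])
    floor = s.min() + 0.25 * (s[i1] - s.min())
    tall = s[lo + 1:hi - 1] >= floor
    cand = np.flatnonzero(interior & tall) + 1
    if len(cand) == 0:
        return p1_time, None, None
    j = int(cand[np.argmax(dsub[cand])])
    i2 = lo + j
    p2_time = _parabolic_refine(d, i2) / fs
    return p1_time, p2_time, "inflection"


def measure_beats(record: PPGRecord,
                  config: Optional[ExtractionConfig] = None) -> List[BeatMeasurement]:
    """Segment a record into beats and measure PPT for each."""
    cfg = config or ExtractionConfig()
    windows = detect_beats(record, cfg)
    if not windows:
        return []
    fs = record.sampling_rate
    smooth = _lowpass(record.samples, fs, cfg.smooth_hz)
    beats: List[BeatMeasurement] = []
    for a, b in windows:
        seg = smooth[a:b]
        p1, p2, kind = locate_peaks(seg, fs, cfg, presmoothed=True)
        foot_t = a / fs
        amplitude = float(seg.max() - seg[0])
        if p2 is None:
            beats.append(BeatMeasurement(
                foot_time=foot_t, p1_time=foot_t + p1, p2_time=None, p2_kind=None,
                ppt=None, beat_len=(b - a) / fs, amplitude=amplitude,
                qc_status="rejected", rejection_reason=REJECT_NO_P2))
            continue
        beats.append(BeatMeasurement(
            foot_time=foot_t, p1_time=foot_t + p1, p2_time=foot_t + p2,
            p2_kind=kind, ppt=(p2 - p1) * 1000.0, beat_len=(b - a) / fs,
            amplitude=amplitude))
    return beats


# --------------------------------------------------------------------------
# quality control
# --------------------------------------------------------------------------

def qc_beats(beats: Sequence[BeatMeasurement],
             rules: Optional[QCRules] = None) -> List[BeatMeasurement]:
    """Reject implausible beats; idempotent.

    Static rules: PPT inside the physiological window, beat length inside
    the allowed interval.  Rolling rules (5-min centred window over beats
    passing the static rules): pulse amplitude z-score and deviation of
    PPT from the rolling median.
    """
    r = rules or QCRules()
    out = [BeatMeasurement(**vars(b)) for b in beats]

    static_ok = []
    for b in out:
        if b.ppt is None:
            b.qc_status, b.rejection_reason = "rejected", b.rejection_reason or REJECT_NO_P2
            static_ok.append(False)
        elif not (r.ppt_window_ms[0] <= b.ppt <= r.ppt_window_ms[1]):
            b.qc_status, b.rejection_reason = "rejected", REJECT_PPT_RANGE
            static_ok.append(False)
        elif not (r.beat_len_s[0] <= b.beat_len <= r.beat_len_s[1]):
            b.qc_status, b.rejection_reason = "rejected", REJECT_BEAT_LEN
            static_ok.append(False)
        elif not (r.upstroke_s[0] <= b.p1_time - b.foot_time <= r.upstroke_s[1]):
            b.qc_status, b.rejection_reason = "rejected", REJECT_UPSTROKE
            static_ok.append(False)
        else:
            static_ok.append(True)
    idx = [i for i, ok in enumerate(static_ok) if ok]
    if not idx:
        return out

    # rolling reference over statically-acceptable beats (stable under re-runs)
    tix = pd.to_timedelta([out[i].foot_time for i in idx], unit="s")
    frame = pd.DataFrame(
        {"amp": [out[i].amplitude for i in idx],
         "ppt": [out[i].ppt for i in idx]},
        index=tix)
    win = f"{int(r.rolling_window_s)}s"
    roll = frame.rolling(win, center=True, min_periods=1)
    # robust centre/scale: artifact bursts inflate a rolling SD enough to
    # mask themselves, so use median and IQR with a relative floor instead
    amp_med = roll["amp"].median().to_numpy()
    iqr = (roll["amp"].quantile(0.75) - roll["amp"].quantile(0.25)).to_numpy()
    amp_scale = np.maximum(iqr / 1.349,
                           r.amp_scale_floor_frac * np.abs(amp_med))
    ppt_med = roll["ppt"].median().to_numpy()

    for k, i in enumerate(idx):
        b = out[i]
        z = (0.0 if amp_scale[k] == 0
             else abs(b.amplitude - amp_med[k]) / amp_scale[k])
        if z > r.amp_z_max:
            b.qc_status, b.rejection_reason = "rejected", REJECT_AMP
        elif abs(b.ppt - ppt_med[k]) > r.ppt_dev_ms:
            b.qc_status, b.rejection_reason = "rejected", REJECT_PPT_DEV
        else:
            b.qc_status, b.rejection_reason = "valid", None
    return out


# --------------------------------------------------------------------------
# overnight averaging and the stiffness index
# --------------------------------------------------------------------------

def average_oppt(beats: Sequence[BeatMeasurement],
                 record: Optional[PPGRecord] = None,
                 config: Optional[ExtractionConfig] = None) -> OvernightSummary:
    """Average valid beats into the overnight PPT.

    ``valid_hours`` is the summed duration of beat windows holding valid
    beats; below the validity floor (default 3 h) the summary is not
    reportable and :class:`InsufficientValidSignal` is raised.
    """
    cfg = config or ExtractionConfig()
    valid = [b for b in beats if b.qc_status == "valid" and b.ppt is not None]
    valid_hours = sum(b.beat_len for b in valid) / 3600.0
    if valid_hours <= cfg.min_valid_hours:
        raise InsufficientValidSignal(valid_hours, cfg.min_valid_hours)
    ppts = np.array([b.ppt for b in valid])
    oppt = float(np.median(ppts)) if cfg.averaging == "median" else float(ppts.mean())
    return OvernightSummary(
        oppt=oppt, osi=None, n_beats_total=len(beats),
        n_beats_valid=len(valid), valid_hours=valid_hours)


def compute_osi(height_cm: float, oppt_ms: float) -> float:
    """OSI (m/s) = body height (m) / overnight PPT (s)."""
    if height_cm <= 0 or oppt_ms <= 0:
        raise ValueError("height and OPPT must be positive")
    return (height_cm / 100.0) / (oppt_ms / 1000.0)


def classify_osi_group(osi: float, threshold: float = 10.9) -> str:
    """Median-split grouping: high when OSI >= threshold, else low."""
    if not np.isfinite(osi):
        raise ValueError("OSI must be finite")
    return "high" if osi >= threshold else "low"


def extract_overnight(record: PPGRecord, height_cm: float,
                      config: Optional[ExtractionConfig] = None,
                      rules: Optional[QCRules] = None,
                      threshold: Optional[float] = None) -> OvernightSummary:
    """Full per-record pipeline: beats -> QC -> OPPT -> OSI (-> group)."""
    beats = qc_beats(measure_beats(record, config), rules)
    summary = average_oppt(beats, record, config)
    summary.osi = compute_osi(height_cm, summary.oppt)
    if threshold is not None:
        summary.osi_group = classify_osi_group(summary.osi, threshold)
    return summary
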