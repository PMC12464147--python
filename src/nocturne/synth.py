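"""Synthetic cohorts, overnight PPG waveforms, and 24-h ABPM series.

The generator emulates a hypertensive cohort undergoing simultaneous
overnight finger photoplethysmography (PPG) and 24-h ambulatory blood
pressure monitoring (ABPM).  A single latent "vascular stiffness" factor
per subject (a z-score) drives every stiffness-sensitive quantity:

* the large-artery reflected-wave speed, hence the per-beat pulse
  propagation time PPT = height / wave_speed;
* ambulatory systolic pressure, pulse pressure, nocturnal dipping
  (inversely), the ambulatory arterial stiffness index (AASI), and the
  apnoea--hypopnea index (AHI).

Every downstream estimate therefore has an exact ground truth
(:class:`CohortTruth`) against which recovery can be tested.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError

# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

MALE = "male"
FEMALE = "female"


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Marginal means/SDs default to values typical of a middle-aged,
    mostly male, mild-to-moderate hypertensive clinic population.
    Effect coefficients are per 1 SD of the latent stiffness factor.
    """

    n_subjects: int = 79
    seed: int = 0

    # --- PPG signal ---
    sampling_rate: float = 100.0          # Hz
    night_hours: float = 7.0              # h
    noise_sd: float = 0.02                # amplitude units (beat amplitude = 1)
    baseline_wander_amp: float = 0.2      # amplitude units
    baseline_wander_hz: float = 0.08      # Hz
    artifact_fraction: float = 0.05       # proportion of the night corrupted
    artifact_amp: float = 4.0             # SD multiplier of burst noise
    mask_artifacts: bool = True           # device-style discard of artifact periods
    heart_rate_bpm: float = 62.0          # cohort mean resting HR
    heart_rate_sd: float = 5.0            # between-subject SD
    hrv_interval_sd: float = 0.03         # within-subject beat interval SD, s
    ppt_beat_sd_ms: float = 4.0           # within-night beat-to-beat PPT SD
    systolic_offset_s: float = 0.18       # foot -> systolic peak
    systolic_width_s: float = 0.030       # Gaussian SD of systolic bump
    reflected_width_s: float = 0.040      # Gaussian SD of reflected bump
    reflected_frac_range: Tuple[float, float] = (0.35, 0.65)

    # --- latent stiffness and its mapping to PPT ---
    latent_stiffness_sd: float = 1.0
    age_stiffness_weight: float = 0.5     # corr(latent, age z-score)
    wave_speed_base: float = 10.9         # m/s at latent = 0
    wave_speed_per_sd: float = 0.30       # m/s per latent SD
    ppt_range_ms: Tuple[float, float] = (100.0, 400.0)

    # --- ABPM ---
    abpm_interval: float = 20.0           # minutes
    abpm_start_hour: float = 10.0         # clock hour recording starts
    bedtime_hour: float = 23.0
    waketime_hour: float = 7.0
    sbp_reading_sd: float = 8.0           # within-period SBP variability, mmHg
    dbp_reading_sd: float = 4.0           # residual DBP noise around the AASI line
    awake_sbp_mean: float = 141.0
    awake_sbp_effect: float = 10.0         # mmHg per latent SD
    awake_sbp_subject_sd: float = 12.0
    pp24_mean: float = 53.0               # 24-h pulse pressure, mmHg
    pp24_effect: float = 3.0              # mmHg per latent SD, on top of the
    pp24_subject_sd: float = 6.0          # 0.4 * SBP24 level coupling
    dipping_mean_pct: float = 14.0        # systolic; diastolic dipping is implied
    dipping_effect_pct: float = 4.4       # reduction per latent SD
    dipping_sd_pct: float = 6.5
    aasi_mean: float = 0.42
    aasi_effect: float = 0.10
    aasi_subject_sd: float = 0.12

    # --- clinical characteristics ---
    age_mean: float = 58.1
    age_sd: float = 10.8
    male_fraction: float = 0.71
    height_mean_cm: Tuple[float, float] = (178.6, 167.2)   # (male, female)
    height_sd_cm: float = 6.5
    bmi_mean: float = 28.1
    bmi_sd: float = 4.0
    smoking_history_fraction: float = 0.36
    current_smoking_given_history: float = 0.5
    diabetes_fraction: float = 0.09
    treatment_fraction: float = 0.51
    tc_mean: float = 5.30
    tc_sd: float = 1.09
    hdl_mean: float = 1.32
    hdl_sd: float = 0.36
    tg_log_mean: float = 0.30             # ln mmol/l
    tg_log_sd: float = 0.45
    creatinine_mean_umol: Tuple[float, float] = (82.0, 68.0)  # (male, female)
    creatinine_sd_umol: Tuple[float, float] = (13.0, 11.0)
    office_sbp_mean: float = 147.0
    office_sbp_effect: float = 4.0
    office_sbp_sd: float = 17.0
    office_pp_mean: float = 57.0
    office_pp_effect: float = 12.0
    office_pp_sd: float = 15.0
    ahi_log_mean: float = 2.1             # ln events/h
    ahi_log_effect: float = 0.60
    ahi_log_sd: float = 0.80

    def validate(self) -> "SimConfig":
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not (0.0 <= self.artifact_fraction < 1.0):
            raise ConfigurationError("artifact_fraction must be in [0, 1)")
        lo, hi = self.ppt_range_ms
        if not (100.0 <= lo < hi <= 400.0):
            raise ConfigurationError("ppt_range_ms must lie within [100, 400] ms")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.night_hours <= 0:
            raise ConfigurationError("night_hours must be positive")
        if self.abpm_interval <= 0:
            raise ConfigurationError("abpm_interval must be positive")
        return self


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class SubjectProfile:
    id: str
    age: float                      # years
    sex: str                        # "male" / "female"
    height: float                   # cm
    weight: float                   # kg
    bmi: float                      # kg/m^2
    smoking_history: bool
    current_smoking: bool
    diabetes: bool
    antihypertensive_treatment: bool
    total_cholesterol: float        # mmol/l
    hdl: float                      # mmol/l
    triglycerides: float            # mmol/l
    creatinine: float               # umol/l
    ahi: float                      # events/h
    office_sbp: float               # mmHg
    office_dbp: float               # mmHg


@dataclass
class NightTruth:
    """Realised beat-level ground truth, filled by :func:`simulate_ppg_night`."""

    beat_foot_times: np.ndarray     # s, foot of every synthesised beat
    beat_ppt_ms: np.ndarray         # true per-beat PPT
    beat_in_artifact: np.ndarray    # bool, beat overlaps an artifact burst
    artifact_spans: np.ndarray      # (k, 2) start/stop seconds


@dataclass
class SubjectTruth:
    index: int
    subject_id: str
    latent_stiffness: float         # z-score
    wave_speed: float               # m/s
    true_mean_ppt: float            # ms
    awake_sbp: float                # mmHg, true period mean
    asleep_sbp: float
    awake_dbp: float
    asleep_dbp: float
    dbp24: float
    systolic_dipping: float         # %
    diastolic_dipping: float        # %, implied by the AASI line
    true_aasi: float                # unitless; regression slope is 1 - AASI
    dbp_intercept: float            # mmHg, intercept of the DBP|SBP line
    night: Optional[NightTruth] = None


@dataclass
class CohortTruth:
    per_subject: List[SubjectTruth]

    def frame(self) -> pd.DataFrame:
        rows = []
        for t in self.per_subject:
            d = dataclasses.asdict(t)
            d.pop("night")
            rows.append(d)
        return pd.DataFrame(rows)

    def __getitem__(self, i: int) -> SubjectTruth:
        return self.per_subject[i]

    def __len__(self) -> int:
        return len(self.per_subject)


@dataclass
class PPGRecord:
    """Uniformly sampled overnight pulse-wave amplitude series."""

    sampling_rate: float
    samples: np.ndarray
    start_time: datetime
    validity_mask: np.ndarray       # True where artifact-free

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.validity_mask = np.asarray(self.validity_mask, dtype=bool)
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if len(self.samples) != len(self.validity_mask):
            raise ConfigurationError("samples and validity_mask must be equal length")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class ABPMRecord:
    """Timestamped SBP/DBP readings plus diary bedtime/wake times."""

    readings: pd.DataFrame          # columns: timestamp, sbp, dbp, valid
    bedtime: Optional[pd.Timestamp]
    waketime: Optional[pd.Timestamp]

    def __post_init__(self):
        df = self.readings
        ts = pd.to_datetime(df["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ConfigurationError("ABPM timestamps must be strictly increasing")


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _rng_for(config: SimConfig, index: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per subject and signal type."""
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(index), int(stream)])
    )


def generate_cohort(config: SimConfig) -> Tuple[List[SubjectProfile], CohortTruth]:
    """Draw a cohort and the latent ground truth of every derived quantity.

    The latent stiffness factor is correlated with age
    (``age_stiffness_weight``) and propagates to the PPT via the
    reflected-wave speed, and to the ABPM side via the configured effect
    coefficients, so that height-normalised OSI tracks the latent factor
    more faithfully than raw pulse propagation time does.
    """
    config.validate()
    rng = _rng_for(config, 0, 0)
    n = config.n_subjects

    age_z = rng.standard_normal(n)
    age = np.clip(config.age_mean + config.age_sd * age_z, 30.0, 88.0)
    w = config.age_stiffness_weight
    latent = (w * age_z + np.sqrt(max(0.0, 1.0 - w * w)) * rng.standard_normal(n))
    latent *= config.latent_stiffness_sd

    male = rng.random(n) < config.male_fraction
    height = np.where(
        male,
        rng.normal(config.height_mean_cm[0], config.height_sd_cm, n),
        rng.normal(config.height_mean_cm[1], config.height_sd_cm, n),
    )
    height = np.round(np.clip(height, 145.0, 205.0), 1)
    bmi_target = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 17.0, 45.0)
    weight = np.round(bmi_target * (height / 100.0) ** 2, 1)
    bmi = weight / (height / 100.0) ** 2

    smoking_hist = rng.random(n) < config.smoking_history_fraction
    current_smoking = smoking_hist & (rng.random(n) < config.current_smoking_given_history)
    diabetes = rng.random(n) < config.diabetes_fraction
    treated = rng.random(n) < config.treatment_fraction

    tc = np.clip(rng.normal(config.tc_mean, config.tc_sd, n), 2.0, 12.0)
    hdl = np.clip(rng.normal(config.hdl_mean, config.hdl_sd, n), 0.5, 3.5)
    tg = np.exp(rng.normal(config.tg_log_mean, config.tg_log_sd, n))
    crea = np.where(
        male,
        rng.normal(config.creatinine_mean_umol[0], config.creatinine_sd_umol[0], n),
        rng.normal(config.creatinine_mean_umol[1], config.creatinine_sd_umol[1], n),
    )
    crea = np.clip(crea, 35.0, 200.0)
    ahi = np.exp(rng.normal(
        config.ahi_log_mean + config.ahi_log_effect * latent, config.ahi_log_sd, n))

    office_sbp = np.clip(
        rng.normal(config.office_sbp_mean + config.office_sbp_effect * latent,
                   config.office_sbp_sd), 95.0, 230.0)
    office_pp = np.clip(
        rng.normal(config.office_pp_mean + config.office_pp_effect * latent,
                   config.office_pp_sd), 20.0, 110.0)
    office_dbp = np.clip(office_sbp - office_pp, 40.0, None)

    # stiffness -> wave speed -> true mean PPT (height-dependent path length)
    speed = np.clip(config.wave_speed_base + config.wave_speed_per_sd * latent, 4.0, 25.0)
    ppt = np.clip(1000.0 * (height / 100.0) / speed, *config.ppt_range_ms)

    # ABPM-side truth
    awake_sbp = rng.normal(config.awake_sbp_mean + config.awake_sbp_effect * latent,
                           config.awake_sbp_subject_sd)
    awake_sbp = np.clip(awake_sbp, 95.0, 220.0)
    dip = np.clip(
        rng.normal(config.dipping_mean_pct - config.dipping_effect_pct * latent,
                   config.dipping_sd_pct), -15.0, 32.0)
    asleep_sbp = awake_sbp * (1.0 - dip / 100.0)
    aasi = np.clip(rng.normal(config.aasi_mean + config.aasi_effect * latent,
                              config.aasi_subject_sd), 0.08, 0.92)
    slope = 1.0 - aasi

    # one DBP|SBP line per subject; intercept fixed by the 24-h DBP target,
    # weighting awake/asleep by diary period durations
    asleep_h = (config.waketime_hour - config.bedtime_hour) % 24.0
    f_asleep = asleep_h / 24.0
    sbp24 = (1.0 - f_asleep) * awake_sbp + f_asleep * asleep_sbp
    # pulse pressure rides partly on pressure level (realistic coupling) and
    # is floored/capped so diastolic pressure stays physiological
    pp24 = (config.pp24_mean + config.pp24_effect * latent
            + 0.4 * (sbp24 - 135.0)
            + config.pp24_subject_sd * rng.standard_normal(n))
    pp24 = np.clip(pp24, 25.0, sbp24 - 58.0)
    dbp24 = sbp24 - pp24
    intercept = dbp24 - slope * sbp24
    awake_dbp = slope * awake_sbp + intercept
    asleep_dbp = slope * asleep_sbp + intercept
    dip_dbp = (awake_dbp - asleep_dbp) / awake_dbp * 100.0

    profiles: List[SubjectProfile] = []
    truths: List[SubjectTruth] = []
    for i in range(n):
        sid = f"S{i + 1:03d}"
        profiles.append(SubjectProfile(
            id=sid,
            age=float(np.round(age[i], 1)),
            sex=MALE if male[i] else FEMALE,
            height=float(height[i]),
            weight=float(weight[i]),
            bmi=float(np.round(bmi[i], 2)),
            smoking_history=bool(smoking_hist[i]),
            current_smoking=bool(current_smoking[i]),
            diabetes=bool(diabetes[i]),
            antihypertensive_treatment=bool(treated[i]),
            total_cholesterol=float(np.round(tc[i], 2)),
            hdl=float(np.round(hdl[i], 2)),
            triglycerides=float(np.round(tg[i], 2)),
            creatinine=float(np.round(crea[i], 1)),
            ahi=float(np.round(ahi[i], 1)),
            office_sbp=float(np.round(office_sbp[i], 1)),
            office_dbp=float(np.round(office_dbp[i], 1)),
        ))
        truths.append(SubjectTruth(
            index=i,
            subject_id=sid,
            latent_stiffness=float(latent[i]),
            wave_speed=float(speed[i]),
            true_mean_ppt=float(ppt[i]),
            awake_sbp=float(awake_sbp[i]),
            asleep_sbp=float(asleep_sbp[i]),
            awake_dbp=float(awake_dbp[i]),
            asleep_dbp=float(asleep_dbp[i]),
            dbp24=float(dbp24[i]),
            systolic_dipping=float(dip[i]),
            diastolic_dipping=float(dip_dbp[i]),
            true_aasi=float(aasi[i]),
            dbp_intercept=float(intercept[i]),
        ))
    return profiles, CohortTruth(truths)


# --------------------------------------------------------------------------
# overnight PPG synthesis
# --------------------------------------------------------------------------

def simulate_ppg_night(subject: SubjectProfile, truth: SubjectTruth,
                       config: SimConfig) -> PPGRecord:
    """Synthesise one overnight two-peak PPG recording.

    Each beat is a systolic Gaussian bump plus a reflected bump delayed by
    the subject's true per-beat PPT, on top of slow baseline wander and
    white noise.  A configurable fraction of the night is replaced by
    contiguous high-amplitude noise bursts (motion-like artifacts); with
    ``mask_artifacts`` those samples are flagged invalid, emulating a
    device that discards artifact periods.

    The realised beat-level ground truth is recorded on ``truth.night``.
    """
    config.validate()
    rng = _rng_for(config, truth.index, 1)
    fs = config.sampling_rate
    duration = config.night_hours * 3600.0
    n_samples = int(round(duration * fs))

    hr = max(35.0, rng.normal(config.heart_rate_bpm, config.heart_rate_sd))
    base_interval = 60.0 / hr

    # beat feet and per-beat true PPT
    n_beats_max = int(duration / (base_interval - 4 * config.hrv_interval_sd)) + 2
    intervals = np.clip(
        base_interval + config.hrv_interval_sd * rng.standard_normal(n_beats_max),
        0.5, 1.4)
    feet = np.concatenate([[0.25], 0.25 + np.cumsum(intervals)])
    feet = feet[feet < duration - 1.2]
    nb = len(feet)
    ppt_ms = truth.true_mean_ppt + config.ppt_beat_sd_ms * rng.standard_normal(nb)
    ppt_ms = np.clip(ppt_ms, *config.ppt_range_ms)

    intervals_real = np.diff(np.append(feet, duration))
    margin = config.systolic_offset_s + 2.0 * config.reflected_width_s
    if np.any(ppt_ms / 1000.0 + margin >= intervals_real):
        raise GenerationError(
            "PPT plus component widths exceed the beat interval; "
            "waveform morphology unresolvable")

    amp2 = rng.uniform(*config.reflected_frac_range)
    t = np.arange(n_samples) / fs
    samples = np.zeros(n_samples)
    s1, s2 = config.systolic_width_s, config.reflected_width_s
    for i in range(nb):
        c1 = feet[i] + config.systolic_offset_s
        c2 = c1 + ppt_ms[i] / 1000.0
        lo = max(0, int((c1 - 4 * s1) * fs))
        hi = min(n_samples, int((c2 + 4 * s2) * fs) + 1)
        tt = t[lo:hi]
        samples[lo:hi] += (np.exp(-0.5 * ((tt - c1) / s1) ** 2)
                           + amp2 * np.exp(-0.5 * ((tt - c2) / s2) ** 2))

    if config.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        samples += config.baseline_wander_amp * np.sin(
            2 * np.pi * config.baseline_wander_hz * t + phase)
    if config.noise_sd > 0:
        samples += config.noise_sd * rng.standard_normal(n_samples)

    # contiguous artifact bursts
    mask = np.ones(n_samples, dtype=bool)
    spans = []
    target = config.artifact_fraction * duration
    covered = 0.0
    guard = 0
    while covered < target and guard < 10000:
        guard += 1
        length = min(rng.uniform(10.0, 60.0), target - covered)
        if length <= 0:
            break
        start = rng.uniform(0.0, duration - length)
        a, b = int(start * fs), int((start + length) * fs)
        if not mask[a:b].all():
            continue
        burst_sd = config.artifact_amp * max(samples.std(), 0.1)
        samples[a:b] = burst_sd * rng.standard_normal(b - a)
        mask[a:b] = False
        spans.append((start, start + length))
        covered += length
    spans_arr = np.array(spans, dtype=float).reshape(-1, 2)

    in_artifact = np.zeros(nb, dtype=bool)
    for a, b in spans_arr:
        in_artifact |= (feet + 1.0 > a) & (feet < b)

    truth.night = NightTruth(
        beat_foot_times=feet,
        beat_ppt_ms=ppt_ms,
        beat_in_artifact=in_artifact,
        artifact_spans=spans_arr,
    )
    start_dt = datetime(2015, 6, 1, int(config.bedtime_hour) % 24, 0, 0)
    return PPGRecord(
        sampling_rate=fs,
        samples=samples,
        start_time=start_dt,
        validity_mask=mask if config.mask_artifacts else np.ones(n_samples, bool),
    )


# --------------------------------------------------------------------------
# ABPM synthesis
# --------------------------------------------------------------------------

def simulate_abpm(subject: SubjectProfile, truth: SubjectTruth,
                  config: SimConfig) -> ABPMRecord:
    """Synthesise a 24-h ABPM series on a fixed reading grid.

    SBP readings are the true period mean plus within-period variability;
    DBP readings lie on the subject's DBP|SBP line (slope ``1 - true
    AASI``) plus residual noise, so the regression-based AASI estimator
    is unbiased for the truth and, with zero noise, period means and
    dipping reproduce the truth exactly.
    """
    config.validate()
    rng = _rng_for(config, truth.index, 2)
    day0 = datetime(2015, 6, 1)
    start = day0 + timedelta(hours=config.abpm_start_hour)
    n_readings = int(round(24 * 60 / config.abpm_interval))
    times = [start + timedelta(minutes=config.abpm_interval * k)
             for k in range(n_readings)]

    bedtime = day0 + timedelta(hours=config.bedtime_hour)
    waketime = day0 + timedelta(hours=config.waketime_hour)
    while waketime <= bedtime:
        waketime += timedelta(days=1)
    if bedtime < start:
        bedtime += timedelta(days=1)
        waketime += timedelta(days=1)

    ts = pd.to_datetime(times)
    asleep = (ts >= bedtime) & (ts < waketime)

    slope = 1.0 - truth.true_aasi
    sbp_mean = np.where(asleep, truth.asleep_sbp, truth.awake_sbp)
    sbp = sbp_mean + config.sbp_reading_sd * rng.standard_normal(n_readings)
    dbp = (slope * sbp + truth.dbp_intercept
           + config.dbp_reading_sd * rng.standard_normal(n_readings))

    df = pd.DataFrame({
        "timestamp": ts,
        "sbp": np.round(sbp, 1),
        "dbp": np.round(dbp, 1),
        "valid": True,
    })
    return ABPMRecord(readings=df, bedtime=pd.Timestamp(bedtime),
                      waketime=pd.Timestamp(waketime))


# --------------------------------------------------------------------------
# plain-text writers / readers
# --------------------------------------------------------------------------

def write_ppg_csv(record: PPGRecord, path) -> None:
    df = pd.DataFrame({"time_s": record.times, "amplitude": record.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_ppg_csv(path, sampling_rate: Optional[float] = None,
                 start_time: Optional[datetime] = None) -> PPGRecord:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    return PPGRecord(
        sampling_rate=sampling_rate,
        samples=df["amplitude"].to_numpy(),
        start_time=start_time or datetime(2000, 1, 1),
        validity_mask=np.ones(len(df), dtype=bool),
    )


def read_ppg_edf(path, channel: int = 0) -> PPGRecord:
    """Read a single-channel PPG trace from an EDF file (requires mne)."""
    import mne  # optional dependency, EDF ingestion only

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[channel]
    return PPGRecord(
        sampling_rate=float(raw.info["sfreq"]),
        samples=np.asarray(data, dtype=float),
        start_time=raw.info["meas_date"] or datetime(2000, 1, 1),
        validity_mask=np.ones(data.shape[0], dtype=bool),
    )


def write_abpm_csv(record: ABPMRecord, path) -> None:
    df = record.readings
    out = pd.DataFrame({
        "timestamp_iso": pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S"),
        "sbp_mmhg": df["sbp"],
        "dbp_mmhg": df["dbp"],
    })
    out.to_csv(path, index=False)


def read_abpm_csv(path, bedtime=None, waketime=None) -> ABPMRecord:
    df = pd.read_csv(path)
    readings = pd.DataFrame({
        "timestamp": pd.to_datetime(df["timestamp_iso"]),
        "sbp": df["sbp_mmhg"].astype(float),
        "dbp": df["dbp_mmhg"].astype(float),
        "valid": True,
    })
    return ABPMRecord(
        readings=readings,
        bedtime=pd.Timestamp(bedtime) if bedtime is not None else None,
        waketime=pd.Timestamp(waketime) if waketime is not None else None,
    )


def write_cohort_csv(profiles: Sequence[SubjectProfile], path) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in profiles]).to_csv(path, index=False)


def read_cohort_csv(path) -> List[SubjectProfile]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {f.name: row[f.name] for f in dataclasses.fields(SubjectProfile)}
        for b in ("smoking_history", "current_smoking", "diabetes",
                  "antihypertensive_treatment"):
            kwargs[b] = bool(kwargs[b])
        kwargs["id"] = str(kwargs["id"])
        kwargs["sex"] = str(kwargs["sex"])
        out.append(SubjectProfile(**kwargs))
    return out


def write_truth_json(truth: CohortTruth, path) -> None:
    rows = []
    for tr in truth.per_subject:
        d = dataclasses.asdict(tr)
        night = d.pop("night")
        if night is not None:
            d["night"] = {k: np.asarray(v).tolist() for k, v in night.items()}
        rows.append(d)
    Path(path).write_text(json.dumps(rows, indent=1))
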