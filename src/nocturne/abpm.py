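"""Period summaries, pulse pressure, dipping, and AASI from 24-h ABPM.

Conventions: the asleep period is the half-open diary interval
``[bedtime, waketime)``; pulse pressure is the difference of period
means (equivalently the mean per-reading difference); dipping is
``(day - night) / day x 100`` on period means; AASI is one minus the
ordinary least-squares slope of diastolic on systolic pressure over all
valid 24-h readings, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (DegenerateRegression, DiaryMissing, EmptyPeriod,
                     RecordUnusable)
from .synth import ABPMRecord

PERIODS = ("24h", "awake", "asleep")


@dataclass
class ValidityLimits:
    """Plausibility filter for single readings (simplified editing rules)."""

    sbp_range: Tuple[float, float] = (60.0, 260.0)
    dbp_range: Tuple[float, float] = (40.0, 150.0)
    pp_range: Tuple[float, float] = (15.0, 120.0)
    min_valid_readings: int = 14


@dataclass
class PeriodSummary:
    sbp: float          # mmHg, mean over valid readings
    dbp: float
    pp: float           # mmHg, sbp - dbp
    n: int


@dataclass
class StiffnessPanel:
    """Per-subject ABPM-derived stiffness / vascular-ageing indices."""

    periods: Dict[str, PeriodSummary]
    systolic_dipping: float     # %
    diastolic_dipping: float    # %
    aasi: float


def validate_readings(record: ABPMRecord,
                      limits: Optional[ValidityLimits] = None) -> ABPMRecord:
    """Flag implausible readings invalid; raise if too few remain."""
    lim = limits or ValidityLimits()
    df = record.readings.copy()
    sbp, dbp = df["sbp"].to_numpy(float), df["dbp"].to_numpy(float)
    pp = sbp - dbp
    ok = ((sbp >= lim.sbp_range[0]) & (sbp <= lim.sbp_range[1])
          & (dbp >= lim.dbp_range[0]) & (dbp <= lim.dbp_range[1])
          & (pp >= lim.pp_range[0]) & (pp <= lim.pp_range[1])
          & (dbp < sbp))
    df["valid"] = ok
    if int(ok.sum()) < lim.min_valid_readings:
        raise RecordUnusable(
            f"only {int(ok.sum())} valid readings "
            f"(>= {lim.min_valid_readings} required)")
    return replace(record, readings=df)


def partition_periods(record: ABPMRecord) -> Dict[str, pd.DataFrame]:
    """Split valid readings into 24-h / awake / asleep sets by diary times."""
    if record.bedtime is None or record.waketime is None:
        raise DiaryMissing("bedtime and wake-up times are required")
    df = record.readings
    valid = df[df["valid"]].copy()
    ts = pd.to_datetime(valid["timestamp"])
    asleep = (ts >= record.bedtime) & (ts < record.waketime)
    return {"24h": valid, "awake": valid[~asleep], "asleep": valid[asleep]}


def period_summary(readings: pd.DataFrame) -> PeriodSummary:
    """Mean SBP/DBP and pulse pressure over one period's valid readings."""
    df = readings[readings["valid"]] if "valid" in readings else readings
    if len(df) == 0:
        raise EmptyPeriod("no valid readings in period")
    sbp = float(df["sbp"].mean())
    dbp = float(df["dbp"].mean())
    return PeriodSummary(sbp=sbp, dbp=dbp, pp=sbp - dbp, n=len(df))


def compute_dipping(day_mean: float, night_mean: float) -> float:
    """Nocturnal fall as a percentage of the awake mean (may be negative)."""
    if day_mean <= 0:
        raise ValueError("day mean must be positive")
    return (day_mean - night_mean) / day_mean * 100.0


def compute_aasi(readings: pd.DataFrame, min_readings: int = 10) -> float:
    """1 minus the OLS slope of DBP on SBP over the full 24-h valid set."""
    df = readings[readings["valid"]] if "valid" in readings else readings
    sbp = df["sbp"].to_numpy(float)
    dbp = df["dbp"].to_numpy(float)
    if len(sbp) < min_readings:
        raise DegenerateRegression(
            f"{len(sbp)} readings (< {min_readings} required)")
    if np.var(sbp) == 0:
        raise DegenerateRegression("zero systolic variance")
    slope = sps.linregress(sbp, dbp).slope
    return 1.0 - float(slope)


def stiffness_panel(record: ABPMRecord,
                    limits: Optional[ValidityLimits] = None) -> StiffnessPanel:
    """Validate, partition, and compute the full per-subject panel."""
    rec = validate_readings(record, limits)
    parts = partition_periods(rec)
    summaries = {p: period_summary(parts[p]) for p in PERIODS}
    return StiffnessPanel(
        periods=summaries,
        systolic_dipping=compute_dipping(summaries["awake"].sbp,
                                         summaries["asleep"].sbp),
        diastolic_dipping=compute_dipping(summaries["awake"].dbp,
                                          summaries["asleep"].dbp),
        aasi=compute_aasi(parts["24h"]),
    )
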