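"""Epoch-level accelerometry: intensity classification, non-wear, day summaries.

Wrist-worn GENEActiv output is modelled at the 10-s epoch summary level:
each epoch carries a signal-vector-magnitude (SVM) value to which
preschool wrist cut points are applied.  The module turns an epoch
series into per-day minutes of sedentary behaviour (SB), light physical
activity (LPA) and moderate-to-vigorous physical activity (MVPA), after
flagging non-wear as long runs of zero counts, and then applies the
cohort inclusion rules and window summaries.

Thresholds are applied on whatever scale the input magnitudes are
declared in; the preschool defaults below are the published wrist values
(printed as "cpm") used unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime

import numpy as np
import pandas as pd

__all__ = [
    "SB",
    "LPA",
    "MVPA",
    "INTENSITY_LABELS",
    "CutPointSet",
    "DOMINANT_CUT_POINTS",
    "NON_DOMINANT_CUT_POINTS",
    "cut_points_for",
    "EpochSeries",
    "DayProfile",
    "classify_epoch_intensity",
    "detect_non_wear",
    "summarize_day",
    "profiles_to_frame",
    "filter_valid_participants",
    "derive_window_minutes",
    "classify_guideline",
]

SB, LPA, MVPA = 0, 1, 2
INTENSITY_LABELS = ("SB", "LPA", "MVPA")

#: UK physical-activity guideline for under-5s: minutes of LPA+MVPA per day.
GUIDELINE_PA_MINUTES = 180.0


@dataclass(frozen=True)
class CutPointSet:
    """Intensity thresholds for one wrist placement.

    SB is everything below ``sb_upper``; LPA is [sb_upper, lpa_upper);
    MVPA is lpa_upper and above.  Half-open intervals guarantee the three
    classes partition [0, inf).
    """

    wrist: str
    sb_upper: float
    lpa_upper: float

    def __post_init__(self):
        if not (0 < self.sb_upper < self.lpa_upper):
            raise ValueError("cut points must satisfy 0 < sb_upper < lpa_upper")


#: Published preschool (3-4 y) wrist cut points for GENEActiv SVM.
DOMINANT_CUT_POINTS = CutPointSet("dominant", sb_upper=8.1, lpa_upper=9.3)
NON_DOMINANT_CUT_POINTS = CutPointSet("non_dominant", sb_upper=5.3, lpa_upper=8.6)


def cut_points_for(wrist: str) -> CutPointSet:
    try:
        return {"dominant": DOMINANT_CUT_POINTS, "non_dominant": NON_DOMINANT_CUT_POINTS}[wrist]
    except KeyError:
        raise ValueError(f"unknown wrist placement {wrist!r}") from None


@dataclass(frozen=True)
class EpochSeries:
    """Uniformly spaced epoch magnitudes for one participant-day (or longer)."""

    participant_id: str
    wrist: str
    start: datetime
    epoch_seconds: int
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("epoch magnitudes must be finite and non-negative")
        if self.epoch_seconds <= 0 or 60 % self.epoch_seconds:
            raise ValueError("epoch_seconds must be positive and divide 60")

    def __len__(self) -> int:
        return self.values.size

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self), freq=f"{self.epoch_seconds}s")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "timestamp": self.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
                "svm": self.values,
                "wrist": self.wrist,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EpochSeries":
        """Rebuild a series from the epoch CSV layout; validates uniform spacing."""
        if frame.empty:
            raise ValueError("empty epoch frame")
        pid = frame["participant_id"].iloc[0]
        wrist = frame["wrist"].iloc[0]
        ts = pd.to_datetime(frame["timestamp"])
        frame = frame.assign(_ts=ts).sort_values("_ts")
        ts = frame["_ts"]
        steps = ts.diff().dropna().dt.total_seconds().to_numpy()
        if steps.size:
            if not np.allclose(steps, steps[0]):
                raise ValueError("epochs must be uniformly spaced")
            epoch_seconds = int(round(steps[0]))
        else:
            epoch_seconds = 10
        return cls(str(pid), str(wrist), ts.iloc[0].to_pydatetime(), epoch_seconds,
                   frame["svm"].to_numpy(float))


@dataclass(frozen=True)
class DayProfile:
    """One participant-day of wear time and behaviour minutes."""

    participant_id: str
    date: _date
    day_type: str  # "weekday" | "weekend"
    wear_min: float
    sb_min: float
    lpa_min: float
    mvpa_min: float

    def __post_init__(self):
        if self.wear_min > 1440 + 1e-9:
            raise ValueError("wear time cannot exceed 1440 min")
        if abs(self.sb_min + self.lpa_min + self.mvpa_min - self.wear_min) > 1e-6:
            raise ValueError("behaviour minutes must sum to wear minutes")


def classify_epoch_intensity(magnitude, cut_points: CutPointSet):
    """Map epoch magnitude(s) to intensity codes (SB=0, LPA=1, MVPA=2).

    SB iff magnitude < sb_upper; LPA iff sb_upper <= magnitude < lpa_upper;
    MVPA otherwise.  Lower bounds are inclusive so every non-negative
    magnitude lands in exactly one class.
    """
    mag = np.asarray(magnitude, dtype=float)
    if np.any(mag < 0):
        raise ValueError("magnitudes must be non-negative")
    codes = np.full(mag.shape, SB, dtype=np.int8)
    codes[mag >= cut_points.sb_upper] = LPA
    codes[mag >= cut_points.lpa_upper] = MVPA
    if np.isscalar(magnitude) or codes.ndim == 0:
        return int(codes)
    return codes


def detect_non_wear(series: EpochSeries, window_minutes: float = 90) -> np.ndarray:
    """Wear mask (True = worn): runs of >= window_minutes consecutive zeros are non-wear.

    The zero-run rule follows the standard count-based non-wear criterion
    for this device at this epoch length.
    """
    if window_minutes * 60 < series.epoch_seconds:
        raise ValueError("non-wear window shorter than one epoch")
    min_run = int(np.ceil(window_minutes * 60 / series.epoch_seconds))
    zero = series.values == 0
    wear = np.ones(len(series), dtype=bool)
    # run-length encode the zero indicator
    edges = np.flatnonzero(np.diff(zero.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [zero.size]))
    for s, e in zip(starts, ends):
        if zero[s] and (e - s) >= min_run:
            wear[s:e] = False
    return wear


def summarize_day(series: EpochSeries, mask: np.ndarray, cut_points: CutPointSet) -> DayProfile:
    """Collapse one day's epochs into wear time and per-intensity minutes.

    Minutes are epoch counts times epoch length; Saturday/Sunday dates are
    weekend days, all others weekdays.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.values.shape:
        raise ValueError("mask must align with the epoch series")
    per_min = series.epoch_seconds / 60.0
    codes = classify_epoch_intensity(series.values[mask], cut_points)
    minutes = [float(np.count_nonzero(codes == k) * per_min) for k in (SB, LPA, MVPA)]
    day = series.start.date()
    return DayProfile(
        participant_id=series.participant_id,
        date=day,
        day_type="weekend" if day.weekday() >= 5 else "weekday",
        wear_min=float(mask.sum() * per_min),
        sb_min=minutes[0],
        lpa_min=minutes[1],
        mvpa_min=minutes[2],
    )


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Stack DayProfile records into the canonical day-profile table."""
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return pd.DataFrame(
        [
            {
                "participant_id": p.participant_id,
                "date": p.date,
                "day_type": p.day_type,
                "wear_min": p.wear_min,
                "sb_min": p.sb_min,
                "lpa_min": p.lpa_min,
                "mvpa_min": p.mvpa_min,
            }
            for p in profiles
        ]
    )


def filter_valid_participants(
    profiles,
    min_days: int = 3,
    min_weekend_days: int = 1,
    min_wear_hours: float = 6.0,
):
    """Apply the cohort inclusion rule and log exclusions.

    A day is valid when wear >= min_wear_hours * 60.  A participant is
    retained when they have at least ``min_days`` valid days of which at
    least ``min_weekend_days`` fall on a weekend.  Returns
    ``(retained_ids, exclusion_log)`` where the log names the failed rule
    for every excluded participant.
    """
    frame = profiles_to_frame(profiles)
    retained: list[str] = []
    log: list[dict] = []
    if frame.empty:
        return retained, log
    for pid, grp in frame.groupby("participant_id", sort=True):
        valid = grp[grp["wear_min"] >= min_wear_hours * 60]
        n_valid = len(valid)
        n_weekend = int((valid["day_type"] == "weekend").sum())
        if n_valid < min_days:
            log.append(
                {
                    "participant_id": pid,
                    "rule": "min_days",
                    "detail": f"{n_valid} valid day(s), need {min_days}",
                }
            )
        elif n_weekend < min_weekend_days:
            log.append(
                {
                    "participant_id": pid,
                    "rule": "min_weekend_days",
                    "detail": f"{n_weekend} valid weekend day(s), need {min_weekend_days}",
                }
            )
        else:
            retained.append(pid)
    return retained, log


_WINDOW_FILTERS = {
    "week": lambda f: f[f["day_type"] == "weekday"],
    "weekend": lambda f: f[f["day_type"] == "weekend"],
    "four_day": lambda f: f,
}


def derive_window_minutes(
    profiles,
    window: str,
    min_wear_hours: float = 6.0,
) -> pd.DataFrame:
    """Per-participant mean daily minutes (SB, LPA, MVPA) over a window.

    ``week`` averages valid weekdays, ``weekend`` valid weekend days,
    ``four_day`` all valid days.  Participants with no valid day in the
    window are dropped from that window's table.
    """
    if window not in _WINDOW_FILTERS:
        raise ValueError(f"unknown window {window!r}; expected one of {sorted(_WINDOW_FILTERS)}")
    frame = profiles_to_frame(profiles)
    frame = frame[frame["wear_min"] >= min_wear_hours * 60]
    frame = _WINDOW_FILTERS[window](frame)
    out = (
        frame.groupby("participant_id", sort=True)[["sb_min", "lpa_min", "mvpa_min"]]
        .mean()
        .reset_index()
    )
    out.insert(1, "window", window)
    return out


def classify_guideline(profiles, min_wear_hours: float = 6.0) -> pd.Series:
    """Per-participant guideline status from mean daily physical activity.

    ``sufficiently_active`` when mean daily LPA+MVPA over valid days
    reaches the 180-min recommendation, else ``insufficiently_active``.
    """
    frame = profiles_to_frame(profiles)
    frame = frame[frame["wear_min"] >= min_wear_hours * 60]
    if frame.empty:
        raise ValueError("no valid days to classify")
    pa = frame.assign(pa_min=frame["lpa_min"] + frame["mvpa_min"])
    mean_pa = pa.groupby("participant_id", sort=True)["pa_min"].mean()
    return mean_pa.map(
        lambda m: "sufficiently_active" if m >= GUIDELINE_PA_MINUTES else "insufficiently_active"
    ).rename("guideline_status")
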