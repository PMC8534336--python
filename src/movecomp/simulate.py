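"""Synthetic cohort generator with known ground truth.

Emulates the measurement chain of a preschool movement-behaviour study:
per-child anthropometrics, day-level 24-h behaviour compositions drawn
logistic-normally on the ilr scale (so the downstream ilr regression is
correctly specified), epoch-level wrist-accelerometer magnitudes
rendered from each day's composition, and motor-competence outcomes
generated from a linear model on ilr coordinates plus age/BMI/sex
covariates with Gaussian noise.

Default calibration
-------------------
The defaults reproduce the descriptive statistics of a published cohort
of 185 British preschoolers (99 boys, 86 girls, aged 3-4): weekday and
weekend mean compositions of (SB, LPA, MVPA) = (559.72, 6.57, 33.71) and
(586.80, 4.60, 8.60) min within a 600-min monitored day, day-level ilr
covariances derived from that cohort's pairwise log-ratio variation
matrices, and outcome coefficients chosen so a 5-min reallocation
between behaviours shifts motor-competence scores by the amounts that
cohort reported (e.g. +2.45 total-MC points for 5 min of LPA in place of
SB on weekdays) and the composition block explains roughly 7-9% of
outcome variance.  All of these are config fields, not hard-coded.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import yaml

from . import coda
from .accelerometry import EpochSeries, cut_points_for

__all__ = [
    "OUTCOMES",
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "RenderedDay",
    "generate_participants",
    "generate_day_compositions",
    "render_epoch_series",
    "generate_fms_outcomes",
    "window_mean_compositions",
    "simulate_cohort",
    "export_cohort",
]

OUTCOMES = ("total_mc", "locomotor", "object_control")

#: Calibration targets: published mean minutes per 600-min monitored day.
WEEK_MEAN_MINUTES = (559.72, 6.57, 33.71)
WEEKEND_MEAN_MINUTES = (586.80, 4.60, 8.60)
FOUR_DAY_MEAN_MINUTES = (570.99, 5.78, 23.23)

#: Published pairwise log-ratio variation (SB-LPA, SB-MVPA, LPA-MVPA).
WEEK_VARIATION = {"sb_lpa": 0.36, "sb_mvpa": 0.22, "lpa_mvpa": 0.52}
WEEKEND_VARIATION = {"sb_lpa": 0.49, "sb_mvpa": 0.93, "lpa_mvpa": 0.99}


def _variation_matrix(v: dict) -> np.ndarray:
    t = np.zeros((3, 3))
    t[0, 1] = t[1, 0] = v["sb_lpa"]
    t[0, 2] = t[2, 0] = v["sb_mvpa"]
    t[1, 2] = t[2, 1] = v["lpa_mvpa"]
    return t


def _default_weekday_cov() -> np.ndarray:
    return coda.ilr_covariance_from_variation(_variation_matrix(WEEK_VARIATION))


def _default_weekend_cov() -> np.ndarray:
    return coda.ilr_covariance_from_variation(_variation_matrix(WEEKEND_VARIATION))


def _default_true_beta() -> dict:
    # (intercept, z1, z2, age, bmi, sex); z-coefficients back-solved from the
    # calibration cohort's 5-min substitution estimates at its weekday centre.
    return {
        "total_mc": np.array([52.648, -3.1027, 4.2904, 3.0, -0.3, 1.5]),
        "locomotor": np.array([34.207, -2.3448, 2.2741, 1.8, -0.2, 0.5]),
        "object_control": np.array([18.571, -0.7699, 2.0114, 1.4, -0.15, 1.0]),
    }


def _default_noise_sd() -> dict:
    # tuned so the composition block explains ~7/8/9% of outcome variance
    # at the default week-window (2-weekday-mean) composition distribution
    return {"total_mc": 6.87, "locomotor": 3.75, "object_control": 2.49}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the calibrated study conditions."""

    n_participants: int = 185
    seed: int = 0
    weekday_mean_comp: tuple = tuple(np.asarray(WEEK_MEAN_MINUTES) / 600.0)
    weekend_mean_comp: tuple = tuple(np.asarray(WEEKEND_MEAN_MINUTES) / 600.0)
    ilr_covariance_weekday: np.ndarray = field(default_factory=_default_weekday_cov)
    ilr_covariance_weekend: np.ndarray = field(default_factory=_default_weekend_cov)
    true_beta: dict = field(default_factory=_default_true_beta)
    noise_sd: dict = field(default_factory=_default_noise_sd)
    epoch_seconds: int = 10
    days: tuple = ("weekday", "weekday", "weekend", "weekend")
    start_date: date = date(2016, 6, 2)  # a Thursday: Thu, Fri, Sat, Sun
    nonwear_block_minutes: float = 0.0
    wear_total_minutes: float = 600.0
    day_to_day_corr: float = 0.0
    sex_counts: tuple = (99, 86)  # (boys, girls)
    quota_sampling: bool = False
    age_range: tuple = (3.0, 4.0)
    height_mean: float = 0.99  # m
    height_sd: float = 0.045
    bmi_mean: float = 16.0  # kg/m^2
    bmi_sd: float = 1.5
    wrist: str = "dominant"
    outcome_window: str = "week"  # window whose composition drives the outcomes

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("weekday_mean_comp", "weekend_mean_comp"):
            comp = np.asarray(getattr(self, name), float)
            if comp.shape != (3,) or np.any(comp <= 0):
                raise ValueError(f"{name} must be 3 strictly positive proportions")
            if abs(comp.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name in ("ilr_covariance_weekday", "ilr_covariance_weekend"):
            cov = np.asarray(getattr(self, name), float)
            if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
                raise ValueError(f"{name} must be a symmetric 2x2 matrix")
            if np.linalg.eigvalsh(cov).min() < 0:
                raise ValueError(f"{name} must be positive semi-definite")
        for out in OUTCOMES:
            if out not in self.true_beta or len(np.atleast_1d(self.true_beta[out])) != 6:
                raise ValueError(f"true_beta[{out!r}] must hold 6 coefficients")
            if self.noise_sd.get(out, 0) < 0:
                raise ValueError("noise_sd must be non-negative")
        if self.epoch_seconds <= 0 or 60 % self.epoch_seconds:
            raise ValueError("epoch_seconds must divide 60")
        if not set(self.days) <= {"weekday", "weekend"}:
            raise ValueError("days entries must be 'weekday' or 'weekend'")
        if not 0 <= self.day_to_day_corr < 1:
            raise ValueError("day_to_day_corr must be in [0, 1)")
        if not 0 < self.wear_total_minutes <= 1440:
            raise ValueError("wear_total_minutes must be in (0, 1440]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def mean_composition(self, day_type: str) -> np.ndarray:
        return np.asarray(
            self.weekday_mean_comp if day_type == "weekday" else self.weekend_mean_comp, float
        )

    def ilr_covariance(self, day_type: str) -> np.ndarray:
        return np.asarray(
            self.ilr_covariance_weekday if day_type == "weekday" else self.ilr_covariance_weekend,
            float,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ilr_covariance_weekday"] = np.asarray(self.ilr_covariance_weekday).tolist()
        d["ilr_covariance_weekend"] = np.asarray(self.ilr_covariance_weekend).tolist()
        d["true_beta"] = {k: np.asarray(v).tolist() for k, v in self.true_beta.items()}
        d["start_date"] = self.start_date.isoformat()
        for key in ("weekday_mean_comp", "weekend_mean_comp", "age_range"):
            d[key] = [float(v) for v in d[key]]
        d["sex_counts"] = [int(v) for v in d["sex_counts"]]
        d["days"] = list(d["days"])
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("ilr_covariance_weekday", "ilr_covariance_weekend"):
            if key in d:
                d[key] = np.asarray(d[key], float)
        if "true_beta" in d:
            d["true_beta"] = {k: np.asarray(v, float) for k, v in d["true_beta"].items()}
        if isinstance(d.get("start_date"), str):
            d["start_date"] = date.fromisoformat(d["start_date"])
        for key in ("weekday_mean_comp", "weekend_mean_comp", "days", "sex_counts", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth kept alongside a synthetic cohort for parameter-recovery checks."""

    config: GeneratorConfig
    day_ilr: pd.DataFrame  # participant_id, date, day_type, z1, z2
    linear_predictor: pd.DataFrame  # participant_id x outcome
    noise: pd.DataFrame  # participant_id x outcome


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame
    day_compositions: pd.DataFrame
    outcomes: pd.DataFrame
    truth: SyntheticTruth

    @property
    def config(self) -> GeneratorConfig:
        return self.truth.config


@dataclass
class RenderedDay:
    series: EpochSeries
    wear_truth: np.ndarray  # True where the device was (synthetically) worn
    epoch_counts: tuple  # epochs emitted per intensity class


def generate_participants(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the participant table: id, age (uniform on the age range), sex, height, mass.

    Sex is binomial with the configured boy:girl ratio by default; quota
    sampling reproduces the exact split (up to rounding for other n).
    """
    rng = config.rng() if rng is None else rng
    n = config.n_participants
    boys, girls = config.sex_counts
    p_male = boys / (boys + girls)
    if config.quota_sampling:
        n_male = int(round(n * p_male))
        sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
        rng.shuffle(sex)
    else:
        sex = np.where(rng.random(n) < p_male, "male", "female")
    age = rng.uniform(*config.age_range, size=n)
    height = np.clip(rng.normal(config.height_mean, config.height_sd, size=n), 0.75, 1.30)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, size=n), 11.0, 25.0)
    mass = bmi * height**2
    width = max(3, len(str(n)))
    return pd.DataFrame(
        {
            "id": [f"P{i+1:0{width}d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "height": height,
            "mass": mass,
            "bmi": bmi,
        }
    )


def generate_day_compositions(
    config: GeneratorConfig,
    participants: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one true composition per participant-day, closed to the wear total.

    Each day's ilr coordinates are Gaussian around the day-type mean
    composition's ilr image with the day-type covariance.  A non-zero
    ``day_to_day_corr`` shares a participant-level random effect across
    days (equicorrelation on the ilr scale).
    """
    rng = config.rng() if rng is None else rng
    n = len(participants)
    rho = config.day_to_day_corr
    u = rng.standard_normal((n, 2))  # shared participant effect (std normal)
    frames = []
    for d_idx, day_type in enumerate(config.days):
        mean = coda.ilr(config.mean_composition(day_type))
        cov = config.ilr_covariance(day_type)
        chol = np.linalg.cholesky(cov + 1e-15 * np.eye(2)) if cov.any() else np.zeros((2, 2))
        e = rng.standard_normal((n, 2))
        z = mean + (np.sqrt(rho) * u + np.sqrt(1 - rho) * e) @ chol.T
        comp = np.atleast_2d(coda.ilr_inverse(z, total=config.wear_total_minutes))
        day = config.start_date + timedelta(days=d_idx)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": participants["id"].to_numpy(),
                    "date": day,
                    "day_type": day_type,
                    "sb_min": comp[:, 0],
                    "lpa_min": comp[:, 1],
                    "mvpa_min": comp[:, 2],
                    "z1": z[:, 0],
                    "z2": z[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _apportion_epochs(minutes: np.ndarray, epochs_per_minute: int) -> np.ndarray:
    """Integer epochs per class by largest remainder, conserving the total."""
    target = minutes * epochs_per_minute
    base = np.floor(target).astype(int)
    short = int(round(target.sum())) - base.sum()
    order = np.argsort(-(target - base))
    base[order[:short]] += 1
    return base


def render_epoch_series(
    day_minutes,
    config: GeneratorConfig,
    rng: np.random.Generator,
    participant_id: str,
    day: date,
    detectable_minutes: float = 90.0,
) -> RenderedDay:
    """Emit a 24-h day of epoch magnitudes realising a behaviour composition.

    Wear epochs get magnitudes drawn uniformly strictly inside the
    intensity band implied by the composition (avoiding threshold ties
    and zeros); the remainder of the 1440-min day is zero-magnitude
    non-wear, placed as a leading and trailing block plus an optional
    mid-day block of ``nonwear_block_minutes``.  Every non-wear block
    must reach ``detectable_minutes`` so that downstream non-wear
    detection recovers the construction exactly.
    """
    minutes = np.asarray(day_minutes, float)
    if minutes.shape != (3,) or np.any(minutes < 0):
        raise ValueError("day_minutes must be 3 non-negative values")
    total = minutes.sum()
    if total > 1440 + 1e-9:
        raise ValueError("composition exceeds the 1440-min day")
    per_min = 60 // config.epoch_seconds
    n_day = 1440 * per_min
    counts = _apportion_epochs(minutes, per_min)
    n_wear = int(counts.sum())
    n_nonwear = n_day - n_wear

    n_mid = int(round(config.nonwear_block_minutes * per_min))
    if n_mid and config.nonwear_block_minutes < detectable_minutes:
        raise ValueError("nonwear_block_minutes shorter than the detection window")
    if n_mid > n_nonwear:
        raise ValueError("composition incompatible with the requested non-wear block")
    n_edge = n_nonwear - n_mid
    n_lead = n_edge // 2
    n_trail = n_edge - n_lead
    for n_block in (n_lead, n_trail):
        if 0 < n_block < detectable_minutes * per_min:
            raise ValueError(
                "composition leaves a residual non-wear block shorter than the "
                "detection window; adjust wear_total_minutes or nonwear_block_minutes"
            )

    cp = cut_points_for(config.wrist)
    bands = [
        (0.02 * cp.sb_upper, 0.98 * cp.sb_upper),
        (cp.sb_upper + 0.02 * (cp.lpa_upper - cp.sb_upper), cp.lpa_upper - 0.02 * (cp.lpa_upper - cp.sb_upper)),
        (1.05 * cp.lpa_upper, 3.0 * cp.lpa_upper),
    ]
    wear_values = np.concatenate(
        [rng.uniform(lo, hi, size=c) for (lo, hi), c in zip(bands, counts)]
    )
    wear_values = rng.permutation(wear_values)

    # mid-day non-wear splits the wear stretch in half
    half = n_wear // 2
    values = np.concatenate(
        [
            np.zeros(n_lead),
            wear_values[:half],
            np.zeros(n_mid),
            wear_values[half:],
            np.zeros(n_trail),
        ]
    )
    wear_truth = values > 0
    series = EpochSeries(
        participant_id=participant_id,
        wrist=config.wrist,
        start=datetime.combine(day, datetime.min.time()),
        epoch_seconds=config.epoch_seconds,
        values=values,
    )
    return RenderedDay(series, wear_truth, tuple(int(c) for c in counts))


def window_mean_compositions(day_compositions: pd.DataFrame, window: str) -> pd.DataFrame:
    """Per-participant arithmetic-mean minutes over a day-type window.

    ``week`` uses weekdays, ``weekend`` weekend days, ``four_day`` all days.
    """
    if window == "week":
        sel = day_compositions[day_compositions["day_type"] == "weekday"]
    elif window == "weekend":
        sel = day_compositions[day_compositions["day_type"] == "weekend"]
    elif window == "four_day":
        sel = day_compositions
    else:
        raise ValueError(f"unknown window {window!r}")
    out = (
        sel.groupby("participant_id", sort=True)[["sb_min", "lpa_min", "mvpa_min"]]
        .mean()
        .reset_index()
    )
    out.insert(1, "window", window)
    return out


def generate_fms_outcomes(
    compositions: pd.DataFrame,
    participants: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
):
    """Motor-competence outcomes from the ilr linear model plus Gaussian noise.

    ``outcome = b0 + b1*z1 + b2*z2 + b_age*age + b_bmi*bmi + b_sex*sex + eps``
    with eps ~ Normal(0, noise_sd^2), sex coded female=0/male=1.  Returns
    ``(outcomes, linear_predictor, noise)`` frames indexed consistently by
    participant.
    """
    rng = config.rng() if rng is None else rng
    comp = compositions.set_index("participant_id")
    part = participants.set_index("id")
    if not comp.index.equals(part.index.sort_values()) and not set(comp.index) == set(part.index):
        raise ValueError("compositions and participants cover different ids")
    part = part.loc[comp.index]
    z = coda.ilr(comp[["sb_min", "lpa_min", "mvpa_min"]].to_numpy())
    sex = part["sex"].map({"female": 0.0, "male": 1.0}).to_numpy()
    design = np.column_stack(
        [np.ones(len(comp)), z[:, 0], z[:, 1], part["age"].to_numpy(), part["bmi"].to_numpy(), sex]
    )
    lin, eps, out = {}, {}, {}
    for name in OUTCOMES:
        beta = np.asarray(config.true_beta[name], float)
        lin[name] = design @ beta
        eps[name] = rng.normal(0.0, config.noise_sd[name], size=len(comp))
        out[name] = lin[name] + eps[name]
    idx = pd.Index(comp.index, name="participant_id")
    return (
        pd.DataFrame(out, index=idx).reset_index(),
        pd.DataFrame(lin, index=idx),
        pd.DataFrame(eps, index=idx),
    )


def simulate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Run the full generative chain (without epoch rendering) under one seed."""
    rng = config.rng()
    participants = generate_participants(config, rng)
    day_comps = generate_day_compositions(config, participants, rng)
    window_comp = window_mean_compositions(day_comps, config.outcome_window)
    outcomes, lin, eps = generate_fms_outcomes(window_comp, participants, config, rng)
    truth = SyntheticTruth(
        config=config,
        day_ilr=day_comps[["participant_id", "date", "day_type", "z1", "z2"]].copy(),
        linear_predictor=lin,
        noise=eps,
    )
    return SyntheticCohort(participants, day_comps, outcomes, truth)


def export_cohort(cohort: SyntheticCohort, outdir, render_epochs: bool = True) -> dict:
    """Write the cohort as CSV/YAML/JSON artefacts; returns the manifest.

    Emits ``participants.csv``, ``outcomes.csv``, ``day_compositions.csv``,
    optionally ``epochs.csv`` (rendered from the true day compositions),
    plus ``config.yaml`` and ``manifest.json`` recording the seed.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = cohort.config
    fmt = "%.10g"
    cohort.participants.to_csv(outdir / "participants.csv", index=False, float_format=fmt)
    cohort.outcomes.to_csv(outdir / "outcomes.csv", index=False, float_format=fmt)
    cohort.day_compositions.to_csv(outdir / "day_compositions.csv", index=False, float_format=fmt)
    n_epoch_rows = 0
    if render_epochs:
        rng = np.random.default_rng(config.seed + 1)  # rendering stream, distinct from cohort stream
        frames = []
        for _, row in cohort.day_compositions.iterrows():
            rendered = render_epoch_series(
                row[["sb_min", "lpa_min", "mvpa_min"]].to_numpy(float),
                config,
                rng,
                participant_id=row["participant_id"],
                day=row["date"] if isinstance(row["date"], date) else date.fromisoformat(str(row["date"])),
            )
            frames.append(rendered.series.to_frame())
        epochs = pd.concat(frames, ignore_index=True)
        epochs.to_csv(outdir / "epochs.csv", index=False, float_format=fmt)
        n_epoch_rows = len(epochs)
    (outdir / "config.yaml").write_text(config.to_yaml())
    manifest = {
        "seed": config.seed,
        "n_participants": int(config.n_participants),
        "n_day_rows": int(len(cohort.day_compositions)),
        "n_epoch_rows": int(n_epoch_rows),
        "files": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
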