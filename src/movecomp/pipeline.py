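"""End-to-end orchestration: epochs -> compositions -> regressions -> tables.

Runs the whole analysis on either a synthetic cohort (generated under a
seed) or user-supplied CSVs, producing the standard artefact set:
descriptive compositions per window, pairwise log-ratio variation
matrices, naive per-behaviour regressions, compositional fits with Wald
tests and diagnostics, 5-min isotemporal-substitution tables, an
exclusion log and a manifest.  All outputs are deterministic under a
fixed seed (no timestamps), so a manifest suffices to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, coda
from .accelerometry import (
    EpochSeries,
    classify_guideline,
    cut_points_for,
    detect_non_wear,
    derive_window_minutes,
    filter_valid_participants,
    profiles_to_frame,
    summarize_day,
)
from .participants import encode_covariates
from .regression import CompositionalOutcomeModel, fit_single_behaviour_regression
from .simulate import (
    OUTCOMES,
    GeneratorConfig,
    export_cohort,
    render_epoch_series,
    simulate_cohort,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "process_epochs",
    "analyse",
    "write_artifacts",
    "render_tables",
    "fit_cohort_window",
]

WINDOWS = ("week", "weekend", "four_day")
BEHAVIOURS = ("sb_min", "lpa_min", "mvpa_min")
BEHAVIOURS_LIST = list(BEHAVIOURS)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for the operator."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    mode: str = "synthetic"  # "synthetic" | "csv"
    input_dir: str | None = None  # csv mode: directory with epochs/participants/outcomes CSVs
    output_dir: str = "movecomp_run"
    windows: tuple = WINDOWS
    delta_minutes: float = 5.0
    closure_total: float = 600.0
    wrist: str = "dominant"
    min_days: int = 3
    min_weekend_days: int = 1
    min_wear_hours: float = 6.0
    nonwear_window_minutes: float = 90.0
    seed: int = 0
    ci: str = "normal"
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides

    def __post_init__(self):
        if self.delta_minutes <= 0:
            raise ValueError("delta_minutes must be positive")
        if self.closure_total <= 0:
            raise ValueError("closure_total must be positive")
        if not self.windows:
            raise ValueError("windows must be non-empty")
        unknown = set(self.windows) - set(WINDOWS)
        if unknown:
            raise ValueError(f"unknown windows: {sorted(unknown)}")
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv" and not self.input_dir:
            raise ValueError("csv mode requires input_dir")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "windows" in d:
            d["windows"] = tuple(d["windows"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = list(self.windows)
        return d

    def generator_config(self) -> GeneratorConfig:
        overrides = dict(self.generator)
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("wrist", self.wrist)
        overrides.setdefault("wear_total_minutes", self.closure_total)
        return GeneratorConfig.from_dict(overrides)


def fit_cohort_window(cohort, window: str, outcome: str, basis=None):
    """Fit the compositional model for one outcome on a cohort's window compositions.

    Convenience bridge from a :class:`~movecomp.simulate.SyntheticCohort`
    (true day compositions, no epoch rendering) straight to a fitted
    :class:`~movecomp.regression.CompositionalOutcomeResults`; used for
    simulation studies where the accelerometry stage is not under test.
    """
    from .simulate import window_mean_compositions

    wc = window_mean_compositions(cohort.day_compositions, window)
    ids = wc["participant_id"]
    cov = encode_covariates(cohort.participants).loc[ids]
    y = cohort.outcomes.set_index("participant_id").loc[ids, outcome].to_numpy()
    model = CompositionalOutcomeModel(
        y, wc[BEHAVIOURS_LIST].to_numpy(), cov, outcome_name=outcome, ids=ids.to_numpy(), basis=basis
    )
    return model.fit()


def process_epochs(epochs: pd.DataFrame, nonwear_window_minutes: float = 90.0) -> pd.DataFrame:
    """Epoch CSV rows -> day-profile table via non-wear detection and cut points.

    Expects columns (participant_id, timestamp, svm, wrist); one
    DayProfile per participant per calendar date.
    """
    required = {"participant_id", "timestamp", "svm", "wrist"}
    if missing := required - set(epochs.columns):
        raise PipelineError("process", f"epoch table missing columns {sorted(missing)}")
    epochs = epochs.assign(_ts=pd.to_datetime(epochs["timestamp"]))
    epochs["_date"] = epochs["_ts"].dt.date
    profiles = []
    for (pid, day), grp in epochs.groupby(["participant_id", "_date"], sort=True):
        series = EpochSeries.from_frame(grp.drop(columns=["_date"]).rename(columns={"_ts": "_ts"}))
        mask = detect_non_wear(series, window_minutes=nonwear_window_minutes)
        profiles.append(summarize_day(series, mask, cut_points_for(series.wrist)))
    return profiles_to_frame(profiles)


def _window_compositions(profiles: pd.DataFrame, retained, window: str, cfg: RunConfig):
    """Retained participants' closed window compositions plus ids."""
    means = derive_window_minutes(profiles, window, min_wear_hours=cfg.min_wear_hours)
    means = means[means["participant_id"].isin(retained)].reset_index(drop=True)
    comps = []
    for _, row in means.iterrows():
        parts = coda.zero_replace(row[list(BEHAVIOURS)].to_numpy(float))
        comps.append(coda.close(parts, cfg.closure_total).parts)
    return means["participant_id"].to_numpy(), np.array(comps)


def analyse(profiles: pd.DataFrame, participants: pd.DataFrame, outcomes: pd.DataFrame,
            config: RunConfig) -> dict:
    """Run filtering, descriptives, variation, regressions and substitution tables."""
    retained, exclusions = filter_valid_participants(
        profiles,
        min_days=config.min_days,
        min_weekend_days=config.min_weekend_days,
        min_wear_hours=config.min_wear_hours,
    )
    if not retained:
        raise PipelineError("filter", "no participants pass the inclusion rules")
    covariates_all = encode_covariates(participants)
    outcomes = outcomes.set_index("participant_id")

    descr_rows, variation, single_rows, comp_fits, iso_frames = [], {}, [], {}, []
    guideline = classify_guideline(
        profiles[profiles["participant_id"].isin(retained)], min_wear_hours=config.min_wear_hours
    )
    for window in config.windows:
        ids, comps = _window_compositions(profiles, retained, window, config)
        if len(ids) < 8:
            raise PipelineError("analyse", f"window {window!r} has too few participants ({len(ids)})")
        centre = coda.geometric_mean_composition(comps, total=config.closure_total)
        for j, part in enumerate(coda.PARTS):
            descr_rows.append(
                {
                    "window": window,
                    "part": part,
                    "min_per_day": centre.parts[j],
                    "proportion": centre.parts[j] / config.closure_total,
                }
            )
        variation[window] = coda.variation_matrix(comps)

        missing_out = set(ids) - set(outcomes.index)
        if missing_out:
            raise PipelineError("analyse", f"outcomes missing for {sorted(missing_out)[:5]}")
        y_frame = outcomes.loc[ids]
        cov = covariates_all.loc[ids]
        comp_fits[window] = {}
        for outcome in OUTCOMES:
            for j, part in enumerate(coda.PARTS):
                sbf = fit_single_behaviour_regression(
                    y_frame[outcome].to_numpy(), comps[:, j], cov,
                    outcome_name=outcome, behaviour_name=part,
                )
                single_rows.append(
                    {
                        "window": window,
                        "outcome": outcome,
                        "behaviour": part,
                        "coef": sbf.coef,
                        "ci_low": sbf.ci95[0],
                        "ci_high": sbf.ci95[1],
                        "pvalue": sbf.pvalue,
                        "rsquared": sbf.rsquared,
                    }
                )
            model = CompositionalOutcomeModel(
                y_frame[outcome].to_numpy(), comps, cov, outcome_name=outcome, ids=ids
            )
            res = model.fit()
            d = res.to_dict()
            diag = res.diagnostics()
            d["diagnostics"] = {
                "normality_pvalue": diag.normality_pvalue,
                "het_pvalue": diag.het_pvalue,
                "n_outliers": diag.n_outliers,
                "outlier_ids": list(diag.outlier_ids),
            }
            comp_fits[window][outcome] = d
            iso = res.isotemporal_table(centre, delta=config.delta_minutes, ci=config.ci)
            iso.insert(0, "window", window)
            iso_frames.append(iso)

    return {
        "config": config.to_dict(),
        "retained_ids": list(retained),
        "exclusions": exclusions,
        "guideline": guideline.reset_index().rename(columns={"index": "participant_id"}),
        "descriptives": pd.DataFrame(descr_rows),
        "variation": variation,
        "single_regressions": pd.DataFrame(single_rows),
        "compositional_fits": comp_fits,
        "isotemporal": pd.concat(iso_frames, ignore_index=True),
        "manifest": {
            "movecomp_version": __version__,
            "seed": config.seed,
            "mode": config.mode,
            "n_participants_in": int(participants.shape[0]),
            "n_retained": len(retained),
            "n_excluded": len(exclusions),
            "n_day_profiles": int(profiles.shape[0]),
            "windows": list(config.windows),
            "config": config.to_dict(),
        },
    }


def run_pipeline(config: RunConfig, export_inputs_to: str | Path | None = None) -> dict:
    """Execute the full pipeline per the run config and return the artefacts.

    In synthetic mode the cohort is generated, rendered to epochs,
    processed back through the accelerometry stage and analysed — the
    epoch round trip is part of the pipeline, not a shortcut.  In csv
    mode ``input_dir`` must hold ``epochs.csv``, ``participants.csv``
    and ``outcomes.csv`` in the package's layouts.
    """
    if config.mode == "synthetic":
        gen_cfg = config.generator_config()
        cohort = simulate_cohort(gen_cfg)
        if export_inputs_to is not None:
            export_cohort(cohort, export_inputs_to, render_epochs=True)
        rng = np.random.default_rng(gen_cfg.seed + 1)  # epoch-rendering stream
        profiles = []
        for _, row in cohort.day_compositions.iterrows():
            rendered = render_epoch_series(
                row[list(BEHAVIOURS)].to_numpy(float), gen_cfg, rng,
                participant_id=row["participant_id"], day=row["date"],
            )
            mask = detect_non_wear(rendered.series, window_minutes=config.nonwear_window_minutes)
            profiles.append(summarize_day(rendered.series, mask, cut_points_for(gen_cfg.wrist)))
        profiles = profiles_to_frame(profiles)
        participants, outcomes = cohort.participants, cohort.outcomes
    else:
        indir = Path(config.input_dir)
        try:
            epochs = pd.read_csv(indir / "epochs.csv")
            participants = pd.read_csv(indir / "participants.csv")
            outcomes = pd.read_csv(indir / "outcomes.csv")
        except FileNotFoundError as err:
            raise PipelineError("load", str(err)) from err
        profiles = process_epochs(epochs, nonwear_window_minutes=config.nonwear_window_minutes)

    return analyse(profiles, participants, outcomes, config)


def write_artifacts(artifacts: dict, outdir) -> None:
    """Serialise the artefact set as CSV/JSON with stable formatting."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    artifacts["descriptives"].to_csv(outdir / "descriptives.csv", index=False, float_format=fmt)
    artifacts["single_regressions"].to_csv(outdir / "single_regressions.csv", index=False, float_format=fmt)
    artifacts["isotemporal"].to_csv(outdir / "isotemporal.csv", index=False, float_format=fmt)
    artifacts["guideline"].to_csv(outdir / "guideline.csv", index=False)
    for window, mat in artifacts["variation"].items():
        pd.DataFrame(mat, index=coda.PARTS, columns=coda.PARTS).to_csv(
            outdir / f"variation_{window}.csv", float_format=fmt
        )
    with open(outdir / "exclusions.jsonl", "w") as fh:
        for rec in artifacts["exclusions"]:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    (outdir / "compositional_fits.json").write_text(
        json.dumps(artifacts["compositional_fits"], indent=2, sort_keys=True)
    )
    (outdir / "manifest.json").write_text(json.dumps(artifacts["manifest"], indent=2, sort_keys=True))


def _fmt_variation(mat: np.ndarray) -> list[str]:
    head = "        " + "".join(f"{p:>8}" for p in coda.PARTS)
    lines = [head]
    for i, p in enumerate(coda.PARTS):
        cells = "".join("       -" if i == j else f"{mat[i, j]:>8.2f}" for j in range(3))
        lines.append(f"{p:<8}" + cells)
    return lines


def render_tables(artifacts: dict) -> str:
    """Human-readable report mirroring the four standard table layouts."""
    for key in ("descriptives", "variation", "single_regressions", "isotemporal"):
        if key not in artifacts:
            raise ValueError(f"missing artefact {key!r}")
    out = ["# Movement-composition analysis report", ""]

    out += ["## Descriptive statistics (central composition per window)", ""]
    descr = artifacts["descriptives"]
    windows = list(dict.fromkeys(descr["window"]))
    header = f"{'':<16}" + "".join(f"{w:>12}" for w in windows)
    out.append(header)
    for part in coda.PARTS:
        row_min = descr[descr["part"] == part].set_index("window")
        out.append(
            f"{part.upper() + ' (min/day)':<16}"
            + "".join(f"{row_min.loc[w, 'min_per_day']:>12.2f}" for w in windows)
        )
        out.append(
            f"{part.upper() + ' (comp)':<16}"
            + "".join(f"{row_min.loc[w, 'proportion']:>12.2f}" for w in windows)
        )
    out.append("")

    out += ["## Behaviour variation matrices", ""]
    for window, mat in artifacts["variation"].items():
        out.append(f"### {window}")
        out += _fmt_variation(np.asarray(mat))
        out.append("")

    out += ["## Per-behaviour linear regressions (standardized B [95% CI], p, r2)", ""]
    for _, r in artifacts["single_regressions"].iterrows():
        star = "*" if r["pvalue"] < 0.05 else " "
        out.append(
            f"{r['window']:<9} {r['outcome']:<15} {r['behaviour']:<5} "
            f"B={r['coef']:+.2f} [{r['ci_low']:+.2f}, {r['ci_high']:+.2f}] "
            f"p={r['pvalue']:.3f}{star} (r2={r['rsquared']:.3f})"
        )
    out.append("")

    if "compositional_fits" in artifacts:
        out += ["## Compositional model fits", ""]
        for window, fits in artifacts["compositional_fits"].items():
            for outcome, d in fits.items():
                w = d["wald"]
                out.append(
                    f"{window:<9} {outcome:<15} r2={d['rsquared']:.3f} "
                    f"partial r2={d['composition_partial_rsquared']:.3f} "
                    f"Wald chi2(2)={w['statistic']:.2f} p={w['pvalue']:.4g}"
                )
        out.append("")

    out += [f"## Isotemporal substitution ({artifacts['isotemporal']['delta_min'].iloc[0]:g} min)", ""]
    iso = artifacts["isotemporal"]
    for outcome in iso["outcome"].unique():
        out.append(f"### {outcome}")
        sub = iso[iso["outcome"] == outcome]
        for _, r in sub.iterrows():
            if r["error"]:
                cell = f"infeasible ({r['error']})"
            else:
                star = "*" if r["significant"] else ""
                cell = f"{r['estimate']:+.2f}{star} ({r['ci_low']:+.2f}, {r['ci_high']:+.2f})"
            out.append(
                f"{r['window']:<9} add {r['add'].upper():<5} remove {r['remove'].upper():<5} {cell}"
            )
        out.append("")
    return "\n".join(out)
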