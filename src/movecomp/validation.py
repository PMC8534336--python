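"""Simulation validation studies for the compositional pipeline.

Monte-Carlo checks that the estimation machinery behaves as advertised
under the generator's known ground truth: substitution estimates agree
with direct model predictions, regression coefficients are recovered
without bias, the composition Wald test holds its nominal size, and the
delta-method substitution intervals achieve their nominal coverage.
Each study takes an explicit seed and replicate count so it can be run
at whatever scale a check warrants.
"""

from __future__ import annotations

import numpy as np

from . import coda
from .pipeline import fit_cohort_window
from .regression import isotemporal_pairs
from .simulate import GeneratorConfig, simulate_cohort

__all__ = [
    "null_composition_config",
    "reallocation_oracle_error",
    "parameter_recovery",
    "wald_type1_rate",
    "reallocation_ci_coverage",
    "basis_invariance_gap",
    "round_trip_errors",
]

ALT_SBP = np.array([[-1, -1, 1], [1, -1, 0]])


def null_composition_config(n: int, seed: int) -> GeneratorConfig:
    """Default study conditions with the composition effect removed from every outcome."""
    cfg = GeneratorConfig(n_participants=n, seed=seed)
    for name, beta in cfg.true_beta.items():
        beta = np.asarray(beta, float).copy()
        beta[1:3] = 0.0
        cfg.true_beta[name] = beta
    return cfg


def reallocation_oracle_error(n_fits: int = 100, seed: int = 0, n: int = 60) -> float:
    """Max |substitution estimate - direct-prediction oracle| over random fits.

    For each replicate a fresh cohort is fitted and one random feasible
    (add, remove, delta) substitution at the sample centre is evaluated
    two ways: through the delta-difference shortcut and through the full
    model prediction at the reallocated composition minus the prediction
    at the baseline.  The two are algebraically identical; the returned
    gap is pure floating-point error.
    """
    rng = np.random.default_rng(seed)
    pairs = isotemporal_pairs()
    worst = 0.0
    for rep in range(n_fits):
        cfg = GeneratorConfig(n_participants=n, seed=int(rng.integers(2**31 - 1)))
        cohort = simulate_cohort(cfg)
        res = fit_cohort_window(cohort, "week", "total_mc")
        week = cohort.day_compositions.query("day_type == 'weekday'")
        baseline = coda.geometric_mean_composition(
            week[["sb_min", "lpa_min", "mvpa_min"]].to_numpy()
        )
        add, remove = pairs[int(rng.integers(len(pairs)))]
        delta = float(rng.uniform(0.1, 0.9) * baseline[remove])
        est = res.predict_reallocation(baseline, add, remove, delta).estimate
        new = coda.reallocate(baseline, add, remove, delta)
        x_new = np.concatenate([[1.0], coda.ilr(new), np.zeros(3)])
        x_old = np.concatenate([[1.0], coda.ilr(baseline), np.zeros(3)])
        direct = float((x_new - x_old) @ res.params.to_numpy())
        worst = max(worst, abs(est - direct))
    return worst


def parameter_recovery(n_reps: int = 200, n: int = 500, seed: int = 0) -> dict:
    """Mean ilr-coefficient estimates over replicates vs truth, in MC-SE units."""
    rng = np.random.default_rng(seed)
    truth = np.asarray(GeneratorConfig().true_beta["total_mc"])[1:3]
    estimates = np.empty((n_reps, 2))
    for rep in range(n_reps):
        cfg = GeneratorConfig(n_participants=n, seed=int(rng.integers(2**31 - 1)))
        res = fit_cohort_window(simulate_cohort(cfg), "week", "total_mc")
        estimates[rep] = res.params[["z1", "z2"]].to_numpy()
    mean = estimates.mean(axis=0)
    mc_se = estimates.std(axis=0, ddof=1) / np.sqrt(n_reps)
    z = (mean - truth) / mc_se
    return {
        "truth": truth,
        "mean_estimate": mean,
        "mc_se": mc_se,
        "z_scores": z,
        "max_abs_z": float(np.max(np.abs(z))),
        "n_reps": n_reps,
        "n": n,
    }


def wald_type1_rate(n_reps: int = 2000, n: int = 200, seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate of the composition Wald test when the true effect is zero."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        cfg = null_composition_config(n, seed=int(rng.integers(2**31 - 1)))
        res = fit_cohort_window(simulate_cohort(cfg), "week", "total_mc")
        rejections += res.wald_composition().pvalue < alpha
    return rejections / n_reps


def reallocation_ci_coverage(n_reps: int = 1000, seed: int = 0, delta: float = 5.0) -> float:
    """Coverage of the 95% substitution CI for a fixed reallocation at defaults.

    The target is the true outcome difference for moving ``delta`` min
    from SB to LPA at the generator's weekday centre composition.
    """
    rng = np.random.default_rng(seed)
    template = GeneratorConfig()
    baseline = coda.close(np.asarray(template.weekday_mean_comp) * 600, 600)
    dz = coda.ilr(coda.reallocate(baseline, "lpa", "sb", delta)) - coda.ilr(baseline)
    truth = float(dz @ np.asarray(template.true_beta["total_mc"])[1:3])
    covered = 0
    for _ in range(n_reps):
        cfg = GeneratorConfig(seed=int(rng.integers(2**31 - 1)))
        res = fit_cohort_window(simulate_cohort(cfg), "week", "total_mc")
        lo, hi = res.predict_reallocation(baseline, "lpa", "sb", delta).ci95
        covered += lo <= truth <= hi
    return covered / n_reps


def basis_invariance_gap(seed: int = 0, n: int = 150) -> float:
    """Worst discrepancy in r2, Wald statistic and substitution estimates across ilr bases."""
    cfg = GeneratorConfig(n_participants=n, seed=seed)
    cohort = simulate_cohort(cfg)
    alt = coda.ilr_basis_from_sbp(ALT_SBP)
    gaps = []
    baseline = coda.geometric_mean_composition(
        cohort.day_compositions[["sb_min", "lpa_min", "mvpa_min"]].to_numpy()
    )
    for outcome in ("total_mc", "locomotor", "object_control"):
        a = fit_cohort_window(cohort, "week", outcome)
        b = fit_cohort_window(cohort, "week", outcome, basis=alt)
        gaps.append(abs(a.rsquared - b.rsquared))
        gaps.append(abs(a.composition_partial_rsquared - b.composition_partial_rsquared))
        gaps.append(abs(a.wald_composition().statistic - b.wald_composition().statistic))
        ta, tb = a.isotemporal_table(baseline), b.isotemporal_table(baseline)
        gaps.append(float(np.nanmax(np.abs(ta["estimate"] - tb["estimate"]))))
    return float(max(gaps))


def round_trip_errors(seed: int = 0) -> dict:
    """Exercise the three structural round trips; returns worst-case errors.

    ilr/ilr-inverse on random compositions; epoch rendering followed by
    non-wear detection and summarisation (error in epoch units per
    class); reallocate-then-reverse.
    """
    from .accelerometry import classify_epoch_intensity, cut_points_for, detect_non_wear, summarize_day

    rng = np.random.default_rng(seed)
    cfg = GeneratorConfig(seed=seed)

    ilr_err = 0.0
    realloc_err = 0.0
    for _ in range(200):
        parts = rng.uniform(0.5, 500, size=3)
        comp = coda.close(parts, 600)
        back = coda.ilr_inverse(coda.ilr(comp), total=600)
        ilr_err = max(ilr_err, float(np.max(np.abs(back.parts - comp.parts))))
        donor = coda.PARTS[int(rng.integers(3))]
        receiver = coda.PARTS[int((coda.PARTS.index(donor) + 1 + rng.integers(2)) % 3)]
        delta = float(rng.uniform(0, 0.9) * comp[donor])
        there = coda.reallocate(comp, receiver, donor, delta)
        back2 = coda.reallocate(there, donor, receiver, delta)
        realloc_err = max(realloc_err, float(np.max(np.abs(back2.parts - comp.parts))))

    epoch_err = 0
    from datetime import date

    for rep in range(10):
        minutes = rng.dirichlet((40, 3, 6)) * 600
        rendered_rng = np.random.default_rng(seed + 100 + rep)
        from .simulate import render_epoch_series

        rendered = render_epoch_series(minutes, cfg, rendered_rng, "P1", date(2016, 6, 2))
        wear = detect_non_wear(rendered.series)
        prof = summarize_day(rendered.series, wear, cut_points_for(cfg.wrist))
        recovered = np.array([prof.sb_min, prof.lpa_min, prof.mvpa_min]) * 6  # epochs
        epoch_err = max(epoch_err, float(np.max(np.abs(recovered - minutes * 6))))

    return {"ilr_round_trip": ilr_err, "epoch_round_trip_epochs": epoch_err, "reallocate_round_trip": realloc_err}
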