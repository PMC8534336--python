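"""Compositional regression: estimation, Wald test, diagnostics, substitution."""

import numpy as np
import pandas as pd
import pytest

from movecomp import coda
from movecomp.coda import close, ilr, ilr_basis_from_sbp
from movecomp.pipeline import fit_cohort_window
from movecomp.regression import (
    CompositionalOutcomeModel,
    fit_single_behaviour_regression,
    isotemporal_pairs,
)
from movecomp.simulate import GeneratorConfig, simulate_cohort

ALT_SBP = np.array([[-1, -1, 1], [1, -1, 0]])


def make_dataset(n=120, seed=5, noise=0.0, beta=(10.0, -3.0, 4.0, 2.0, -0.5, 1.0)):
    """Synthetic regression dataset with a fully known linear truth."""
    rng = np.random.default_rng(seed)
    comps = rng.dirichlet((50, 4, 8), size=n) * 600
    z = ilr(comps)
    cov = np.column_stack(
        [rng.uniform(3, 4, n), rng.normal(16, 1.5, n), (rng.random(n) < 0.5).astype(float)]
    )
    design = np.column_stack([np.ones(n), z, cov])
    y = design @ np.asarray(beta) + rng.normal(0, noise, n)
    return y, comps, cov, np.asarray(beta)


class TestFit:
    def test_zero_noise_recovers_truth_exactly(self):
        y, comps, cov, beta = make_dataset(noise=0.0)
        res = CompositionalOutcomeModel(y, comps, cov).fit()
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-8)
        assert res.rsquared == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        y, comps, cov, _ = make_dataset(noise=2.0)
        res = CompositionalOutcomeModel(y, comps, cov).fit()
        perm = np.random.default_rng(0).permutation(len(y))
        res_p = CompositionalOutcomeModel(y[perm], comps[perm], cov[perm]).fit()
        assert np.allclose(res.params, res_p.params, atol=1e-10)
        assert np.allclose(res.cov_params, res_p.cov_params, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        y, comps, cov, _ = make_dataset(n=50)
        cov = cov.copy()
        cov[:, 2] = 1.0  # sex constant -> collinear with the intercept
        with pytest.raises(np.linalg.LinAlgError, match="sex"):
            CompositionalOutcomeModel(y, comps, cov).fit()

    def test_too_few_rows_rejected(self):
        y, comps, cov, _ = make_dataset(n=6)
        with pytest.raises(ValueError):
            CompositionalOutcomeModel(y, comps, cov)

    def test_from_dataframe(self):
        y, comps, cov, _ = make_dataset(n=30)
        frame = pd.DataFrame(
            np.column_stack([y, comps, cov]),
            columns=["total_mc", "sb_min", "lpa_min", "mvpa_min", "age", "bmi", "sex"],
        )
        res = CompositionalOutcomeModel.from_dataframe(frame, "total_mc").fit()
        assert res.nobs == 30
        assert "total_mc" in res.summary()


class TestWaldTest:
    def test_zero_coefficient_vector_gives_zero_statistic(self):
        # craft an outcome whose least-squares z-coefficients are exactly
        # zero while the residual variance stays positive: a covariate-only
        # signal plus noise projected orthogonal to the whole design
        rng = np.random.default_rng(6)
        _, comps, cov, _ = make_dataset(n=100, seed=6)
        design = np.column_stack([np.ones(100), ilr(comps), cov])
        raw = rng.normal(size=100)
        resid = raw - design @ np.linalg.lstsq(design, raw, rcond=None)[0]
        y = np.column_stack([np.ones(100), cov]) @ np.array([10.0, 2.0, -0.5, 1.0]) + resid
        res = CompositionalOutcomeModel(y, comps, cov).fit()
        w = res.wald_composition()
        assert w.statistic == pytest.approx(0.0, abs=1e-12)
        assert w.pvalue == pytest.approx(1.0)
        assert w.df == 2

    def test_statistic_invariant_to_basis(self):
        y, comps, cov, _ = make_dataset(noise=2.0)
        w1 = CompositionalOutcomeModel(y, comps, cov).fit().wald_composition()
        w2 = (
            CompositionalOutcomeModel(y, comps, cov, basis=ilr_basis_from_sbp(ALT_SBP))
            .fit()
            .wald_composition()
        )
        assert w1.statistic == pytest.approx(w2.statistic, abs=1e-8)


class TestDiagnostics:
    def test_clean_linear_data_flags_nothing(self):
        y, comps, cov, _ = make_dataset(noise=0.5, n=200)
        diag = CompositionalOutcomeModel(y, comps, cov).fit().diagnostics()
        assert diag.n_outliers == 0

    def test_planted_outlier_flagged(self):
        y, comps, cov, _ = make_dataset(noise=1.0, n=200, seed=8)
        y = y.copy()
        y[17] += 10.0 * 1.0  # 10 residual SDs
        diag = CompositionalOutcomeModel(y, comps, cov, ids=np.arange(200)).fit().diagnostics()
        assert 17 in diag.outlier_ids

    def test_gaussian_residual_normality_rejected_at_alpha_rate(self):
        rejections = 0
        n_rep = 300
        for rep in range(n_rep):
            y, comps, cov, _ = make_dataset(n=120, seed=1000 + rep, noise=2.0)
            diag = CompositionalOutcomeModel(y, comps, cov).fit().diagnostics()
            rejections += diag.normality_pvalue < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.04)

    def test_small_sample_reports_not_applicable(self):
        y, comps, cov, _ = make_dataset(n=7, seed=3)
        diag = CompositionalOutcomeModel(y, comps, cov).fit().diagnostics()
        assert diag.normality_stat is None and diag.notes


class TestSingleBehaviour:
    def test_null_behaviour_coefficient_near_zero(self):
        rng = np.random.default_rng(4)
        n = 4000
        x = rng.uniform(0, 100, n)
        cov = np.column_stack([rng.uniform(3, 4, n), rng.normal(16, 1.5, n), rng.integers(0, 2, n)])
        y = cov @ np.array([2.0, -0.5, 1.0]) + rng.normal(0, 3, n)
        fit = fit_single_behaviour_regression(y, x, cov)
        assert abs(fit.coef) < 0.05

    def test_row_duplication_shrinks_se_analytically(self):
        y, comps, cov, _ = make_dataset(noise=3.0, n=80)
        x = comps[:, 1]
        one = fit_single_behaviour_regression(y, x, cov)
        two = fit_single_behaviour_regression(
            np.tile(y, 2), np.tile(x, 2), np.tile(cov, (2, 1))
        )
        assert two.coef == pytest.approx(one.coef, rel=1e-10)
        n, p = 80, 5
        se1 = (one.ci95[1] - one.ci95[0]) / 2
        se2 = (two.ci95[1] - two.ci95[0]) / 2
        # duplicating data: Gram doubles, RSS doubles, df goes n-p -> 2n-p;
        # the large-sample SE ratio is sqrt((n-p)/(2n-p)) up to the t critical value
        import scipy.stats as st

        expected = np.sqrt((n - p) / (2 * n - p)) * st.t.ppf(0.975, 2 * n - p) / st.t.ppf(0.975, n - p)
        assert se2 / se1 == pytest.approx(expected, rel=1e-6)

    def test_standardized_coefficient_unit_invariant(self):
        y, comps, cov, _ = make_dataset(noise=3.0)
        minutes = fit_single_behaviour_regression(y, comps[:, 2], cov)
        hours = fit_single_behaviour_regression(y, comps[:, 2] / 60.0, cov)
        assert minutes.coef == pytest.approx(hours.coef, rel=1e-12)

    def test_zero_variance_rejected(self):
        y, comps, cov, _ = make_dataset(n=20)
        with pytest.raises(ValueError):
            fit_single_behaviour_regression(y, np.full(20, 5.0), cov)


@pytest.fixture(scope="module")
def fitted():
    y, comps, cov, _ = make_dataset(noise=2.0, n=150, seed=10)
    res = CompositionalOutcomeModel(y, comps, cov).fit()
    baseline = coda.geometric_mean_composition(comps, total=600)
    return res, baseline


class TestReallocationPrediction:

    def test_zero_delta_zero_estimate(self, fitted):
        res, baseline = fitted
        est = res.predict_reallocation(baseline, "lpa", "sb", 0.0)
        assert est.estimate == 0.0 and est.ci95 == (0.0, 0.0)

    def test_matches_direct_prediction_oracle(self, fitted):
        res, baseline = fitted
        # oracle: full-model prediction at the reallocated composition minus
        # prediction at the baseline, covariates held fixed
        cov_fixed = np.array([3.5, 16.0, 1.0])
        for add, remove in isotemporal_pairs():
            new = coda.reallocate(baseline, add, remove, 5.0)
            direct = (
                np.concatenate([[1.0], ilr(new), cov_fixed])
                - np.concatenate([[1.0], ilr(baseline), cov_fixed])
            ) @ res.params.to_numpy()
            est = res.predict_reallocation(baseline, add, remove, 5.0)
            assert est.estimate == pytest.approx(direct, abs=1e-9)

    def test_asymmetry_of_opposite_swaps(self, fitted):
        res, baseline = fitted
        ab = res.predict_reallocation(baseline, "lpa", "sb", 5.0).estimate
        ba = res.predict_reallocation(baseline, "sb", "lpa", 5.0).estimate
        assert ab != pytest.approx(-ba, rel=1e-6)

    def test_estimate_linear_in_coefficients(self, fitted):
        res, baseline = fitted
        dz = ilr(coda.reallocate(baseline, "mvpa", "sb", 5.0)) - ilr(baseline)
        expected = float(dz @ res.params[["z1", "z2"]].to_numpy())
        assert res.predict_reallocation(baseline, "mvpa", "sb", 5.0).estimate == pytest.approx(expected)

    def test_continuity_as_delta_vanishes(self, fitted):
        res, baseline = fitted
        small = res.predict_reallocation(baseline, "lpa", "sb", 1e-7)
        assert abs(small.estimate) < 1e-6

    def test_t_interval_wider_than_normal(self, fitted):
        res, baseline = fitted
        znorm = res.predict_reallocation(baseline, "lpa", "sb", 5.0)
        tt = res.predict_reallocation(baseline, "lpa", "sb", 5.0, ci="t")
        assert (tt.ci95[1] - tt.ci95[0]) > (znorm.ci95[1] - znorm.ci95[0])


class TestIsotemporalTable:
    def test_six_ordered_pairs(self):
        y, comps, cov, _ = make_dataset(noise=2.0)
        res = CompositionalOutcomeModel(y, comps, cov).fit()
        table = res.isotemporal_table(coda.geometric_mean_composition(comps))
        assert len(table) == 6
        assert set(zip(table["add"], table["remove"])) == set(isotemporal_pairs())

    def test_infeasible_cell_isolated(self):
        y, comps, cov, _ = make_dataset(noise=2.0)
        res = CompositionalOutcomeModel(y, comps, cov).fit()
        baseline = close((586.80, 4.60, 8.60), 600)  # LPA below the 5-min delta
        table = res.isotemporal_table(baseline, delta=5.0)
        bad = table[table["remove"] == "lpa"]
        good = table[table["remove"] != "lpa"]
        assert bad["estimate"].isna().all() and bad["error"].str.contains("infeasible").all()
        assert good["estimate"].notna().all() and (good["error"] == "").all()

    def test_matches_cellwise_oracle_on_synthetic_truth(self):
        cfg = GeneratorConfig(n_participants=400, seed=33)
        cfg.noise_sd = {k: 1e-9 for k in cfg.noise_sd}
        res = fit_cohort_window(simulate_cohort(cfg), "week", "total_mc")
        baseline = close((559.72, 6.57, 33.71), 600)
        beta_z = np.asarray(cfg.true_beta["total_mc"])[1:3]
        table = res.isotemporal_table(baseline)
        for _, row in table.iterrows():
            dz = ilr(coda.reallocate(baseline, row["add"], row["remove"], 5.0)) - ilr(baseline)
            assert row["estimate"] == pytest.approx(float(dz @ beta_z), abs=1e-4)


class TestBasisInvariance:
    def test_fit_quality_and_substitution_invariant(self):
        cfg = GeneratorConfig(n_participants=150, seed=44)
        cohort = simulate_cohort(cfg)
        res_a = fit_cohort_window(cohort, "week", "total_mc")
        res_b = fit_cohort_window(cohort, "week", "total_mc", basis=ilr_basis_from_sbp(ALT_SBP))
        assert res_a.rsquared == pytest.approx(res_b.rsquared, abs=1e-10)
        assert res_a.composition_partial_rsquared == pytest.approx(
            res_b.composition_partial_rsquared, abs=1e-10
        )
        assert res_a.wald_composition().statistic == pytest.approx(
            res_b.wald_composition().statistic, abs=1e-8
        )
        baseline = coda.geometric_mean_composition(
            cohort.day_compositions[["sb_min", "lpa_min", "mvpa_min"]].to_numpy()
        )
        ta = res_a.isotemporal_table(baseline)
        tb = res_b.isotemporal_table(baseline)
        assert np.allclose(ta["estimate"], tb["estimate"], atol=1e-8)
        assert np.allclose(ta["ci_low"], tb["ci_low"], atol=1e-8)
        # individual coefficients are basis-dependent, as expected
        assert not np.allclose(res_a.params[["z1", "z2"]], res_b.params[["z1", "z2"]])
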