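"""ilr regression of motor-competence outcomes on movement compositions.

The central model of the package.  A behaviour composition (SB, LPA,
MVPA) enters an ordinary linear model through its two isometric
log-ratio coordinates, alongside age, BMI and sex:

    outcome = b0 + b1*z1 + b2*z2 + b_age*age + b_bmi*bmi + b_sex*sex + eps

The composition's joint contribution is judged by a Wald chi-square test
of (b1, b2) after the covariates (the Type II / marginality construction
for this single-block model), and isotemporal substitution converts the
fitted coefficients into the predicted outcome change for moving a fixed
number of minutes between two behaviours, with delta-method confidence
intervals.  Because ilr is nonlinear in minutes, the effect of "+5 A, -5
B" is not the negative of "+5 B, -5 A".

The API follows the model/results idiom: build a
:class:`CompositionalOutcomeModel` from data, call :meth:`fit`, and use
the returned :class:`CompositionalOutcomeResults` for tests, diagnostics,
substitution estimates and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from . import coda
from .coda import BehaviourComposition

__all__ = [
    "CompositionalOutcomeModel",
    "CompositionalOutcomeResults",
    "WaldTestResult",
    "ReallocationEstimate",
    "DiagnosticsReport",
    "SingleBehaviourFit",
    "fit_single_behaviour_regression",
    "isotemporal_pairs",
]

COVARIATES = ("age", "bmi", "sex")
PARAM_NAMES = ("intercept", "z1", "z2") + COVARIATES

#: The six ordered (add, remove) behaviour pairs of a 3-part substitution table.
def isotemporal_pairs(labels=coda.PARTS):
    return [(a, r) for a in labels for r in labels if a != r]


@dataclass(frozen=True)
class WaldTestResult:
    statistic: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class ReallocationEstimate:
    """Predicted outcome difference for a single +delta/-delta behaviour swap."""

    outcome: str
    add_behaviour: str
    remove_behaviour: str
    delta: float
    estimate: float
    se: float
    ci95: tuple

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return lo > 0 or hi < 0


@dataclass(frozen=True)
class DiagnosticsReport:
    """Advisory residual diagnostics; the pipeline never auto-drops points."""

    normality_stat: float | None
    normality_pvalue: float | None
    het_stat: float | None
    het_pvalue: float | None
    outlier_ids: tuple
    n_outliers: int
    notes: tuple = ()


class CompositionalOutcomeModel:
    """Linear model of one outcome on ilr(composition) plus (age, bmi, sex).

    Parameters
    ----------
    outcome : array-like
        Outcome values, one per participant.
    compositions : (n, 3) array-like
        Strictly positive (SB, LPA, MVPA) parts; any totals (ilr is
        closure-invariant).
    covariates : (n, 3) array-like or DataFrame
        Columns (age, bmi, sex) with sex coded female=0/male=1.
    basis : (3, 2) array, optional
        Orthonormal ilr contrast matrix; defaults to the package basis
        {SB | LPA, MVPA}, {LPA | MVPA}.  Fit quality, the composition
        Wald test and substitution estimates are invariant to this
        choice; individual z-coefficients are not.
    """

    def __init__(self, outcome, compositions, covariates, *, basis=None,
                 outcome_name: str = "outcome", ids=None):
        y = np.asarray(outcome, float)
        comps = np.asarray(compositions, float)
        if isinstance(covariates, pd.DataFrame):
            covariates = covariates[list(COVARIATES)].to_numpy(float)
        x_cov = np.asarray(covariates, float)
        n = y.shape[0]
        if y.ndim != 1:
            raise ValueError("outcome must be 1-D")
        if comps.shape != (n, 3) or x_cov.shape != (n, len(COVARIATES)):
            raise ValueError("outcome, compositions and covariates must align row-wise")
        if np.isnan(y).any() or np.isnan(comps).any() or np.isnan(x_cov).any():
            raise ValueError("missing values are not allowed")
        if n <= 6:
            raise ValueError("need more observations than the 6 parameters")
        self.basis = coda.default_ilr_basis(3) if basis is None else np.asarray(basis, float)
        self.outcome_name = outcome_name
        self.ids = np.asarray(ids) if ids is not None else np.arange(n)
        self.endog = y
        self.compositions = comps
        self.ilr_coords = coda.ilr(comps, basis=self.basis)
        self.covariates = x_cov
        self.exog = np.column_stack([np.ones(n), self.ilr_coords, x_cov])

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome_col: str,
                       part_cols=("sb_min", "lpa_min", "mvpa_min"),
                       covariate_cols=COVARIATES, id_col=None, basis=None):
        ids = data[id_col].to_numpy() if id_col else None
        return cls(
            data[outcome_col].to_numpy(float),
            data[list(part_cols)].to_numpy(float),
            data[list(covariate_cols)].to_numpy(float),
            basis=basis,
            outcome_name=outcome_col,
            ids=ids,
        )

    def fit(self) -> "CompositionalOutcomeResults":
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            # name the offending columns for the caller
            bad = []
            for j in range(self.exog.shape[1]):
                others = np.delete(self.exog, j, axis=1)
                if np.linalg.matrix_rank(others) == rank:
                    bad.append(PARAM_NAMES[j])
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient; collinear column(s): {bad}"
            )
        res = sm.OLS(self.endog, self.exog).fit()
        # reduced model (covariates only) for the composition's partial r^2
        reduced = sm.OLS(self.endog, np.column_stack([np.ones(len(self.endog)), self.covariates])).fit()
        return CompositionalOutcomeResults(self, res, reduced)


class CompositionalOutcomeResults:
    """Fitted ilr regression: estimates, uncertainty, tests and substitution."""

    def __init__(self, model: CompositionalOutcomeModel, olsres, reduced_olsres):
        self.model = model
        self._res = olsres
        self._reduced = reduced_olsres
        self.params = pd.Series(olsres.params, index=PARAM_NAMES)
        self.bse = pd.Series(olsres.bse, index=PARAM_NAMES)
        self.pvalues = pd.Series(olsres.pvalues, index=PARAM_NAMES)
        self.cov_params = pd.DataFrame(olsres.cov_params(), index=PARAM_NAMES, columns=PARAM_NAMES)
        self.nobs = int(olsres.nobs)
        self.df_resid = int(olsres.df_resid)
        self.rsquared = float(olsres.rsquared)
        #: increment in r^2 from adding the ilr pair to the covariate-only model
        self.composition_partial_rsquared = float(olsres.rsquared - reduced_olsres.rsquared)
        self.resid = np.asarray(olsres.resid)
        self.fittedvalues = np.asarray(olsres.fittedvalues)
        self.scale = float(olsres.scale)  # residual variance (RSS / df_resid)

    # -- inference --------------------------------------------------------

    def wald_composition(self) -> WaldTestResult:
        """Joint Wald chi-square test of the two ilr coefficients (df = 2).

        Tests the composition block after all covariates — the Type II
        construction under marginality for a model with a single
        composition term.
        """
        b = self.params[["z1", "z2"]].to_numpy()
        v = self.cov_params.loc[["z1", "z2"], ["z1", "z2"]].to_numpy()
        try:
            stat = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError("singular covariance block for (z1, z2)") from None
        return WaldTestResult(stat, 2, float(st.chi2.sf(stat, 2)))

    def diagnostics(self, outlier_threshold: float = 3.0) -> DiagnosticsReport:
        """Residual checks: normality, heteroscedasticity, outliers.

        Shapiro-Wilk on residuals; an LM test regressing squared
        residuals on fitted values; studentized-residual flags at
        |r| > threshold.  Tests that need more data than available are
        reported as not applicable.
        """
        notes = []
        resid = self.resid
        n = resid.size
        if n >= 8:
            w, p_norm = st.shapiro(resid if n <= 4999 else resid[:4999])
            norm_stat, norm_p = float(w), float(p_norm)
        else:
            norm_stat = norm_p = None
            notes.append("normality test not applicable (n < 8)")
        if n >= 10 and np.var(self.fittedvalues) > 0:
            aux = sm.OLS(resid**2, sm.add_constant(self.fittedvalues)).fit()
            het_stat = float(n * aux.rsquared)
            het_p = float(st.chi2.sf(het_stat, 1))
        else:
            het_stat = het_p = None
            notes.append("heteroscedasticity test not applicable")
        influence = self._res.get_influence()
        student = influence.resid_studentized_internal
        flags = np.abs(student) > outlier_threshold
        return DiagnosticsReport(
            normality_stat=norm_stat,
            normality_pvalue=norm_p,
            het_stat=het_stat,
            het_pvalue=het_p,
            outlier_ids=tuple(np.asarray(self.model.ids)[flags].tolist()),
            n_outliers=int(flags.sum()),
            notes=tuple(notes),
        )

    # -- isotemporal substitution -----------------------------------------

    def _crit(self, ci: str) -> float:
        if ci == "normal":
            return float(st.norm.ppf(0.975))
        if ci == "t":
            return float(st.t.ppf(0.975, self.df_resid))
        raise ValueError("ci must be 'normal' or 't'")

    def predict_reallocation(self, baseline, add: str, remove: str, delta: float,
                             ci: str = "normal") -> ReallocationEstimate:
        """Predicted outcome change for moving ``delta`` min from one behaviour to another.

        The reallocated composition's ilr coordinates are differenced
        against the baseline's; the estimate is ``dz @ b_comp`` (the
        covariate terms cancel), its variance ``dz @ V_comp @ dz`` by the
        delta method, and the 95% CI uses the normal critical value by
        default (``ci='t'`` switches to the t quantile on the residual df).
        """
        base = baseline if isinstance(baseline, BehaviourComposition) else coda.close(
            np.asarray(baseline, float), float(np.sum(baseline))
        )
        if delta == 0:
            return ReallocationEstimate(self.model.outcome_name, add, remove, 0.0, 0.0, 0.0, (0.0, 0.0))
        new = coda.reallocate(base, add, remove, delta)
        dz = coda.ilr(new, basis=self.model.basis) - coda.ilr(base, basis=self.model.basis)
        b = self.params[["z1", "z2"]].to_numpy()
        v = self.cov_params.loc[["z1", "z2"], ["z1", "z2"]].to_numpy()
        est = float(dz @ b)
        se = float(np.sqrt(dz @ v @ dz))
        crit = self._crit(ci)
        return ReallocationEstimate(
            self.model.outcome_name, add, remove, float(delta), est, se,
            (est - crit * se, est + crit * se),
        )

    def isotemporal_table(self, baseline, delta: float = 5.0, ci: str = "normal") -> pd.DataFrame:
        """All six ordered (add, remove) substitutions at one baseline.

        Cells whose reallocation is infeasible on the raw-minute scale
        (the donor behaviour holds <= delta minutes at the baseline) are
        reported with NaN estimates and an ``error`` note; the other
        cells are unaffected.
        """
        rows = []
        for add, remove in isotemporal_pairs():
            try:
                e = self.predict_reallocation(baseline, add, remove, delta, ci=ci)
                rows.append(
                    {
                        "outcome": e.outcome,
                        "add": add,
                        "remove": remove,
                        "delta_min": e.delta,
                        "estimate": e.estimate,
                        "ci_low": e.ci95[0],
                        "ci_high": e.ci95[1],
                        "significant": e.significant,
                        "error": "",
                    }
                )
            except coda.InfeasibleReallocationError as err:
                rows.append(
                    {
                        "outcome": self.model.outcome_name,
                        "add": add,
                        "remove": remove,
                        "delta_min": float(delta),
                        "estimate": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "significant": False,
                        "error": str(err),
                    }
                )
        return pd.DataFrame(rows)

    # -- reporting ---------------------------------------------------------

    def to_dict(self) -> dict:
        wald = self.wald_composition()
        return {
            "outcome": self.model.outcome_name,
            "n": self.nobs,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "cov_params": self.cov_params.to_numpy().tolist(),
            "rsquared": self.rsquared,
            "composition_partial_rsquared": self.composition_partial_rsquared,
            "wald": {"statistic": wald.statistic, "df": wald.df, "pvalue": wald.pvalue},
        }

    def summary(self) -> str:
        wald = self.wald_composition()
        lines = [
            f"Compositional linear model: {self.model.outcome_name} ~ z1 + z2 + age + bmi + sex",
            f"n = {self.nobs}   r2 = {self.rsquared:.4f}   "
            f"composition partial r2 = {self.composition_partial_rsquared:.4f}",
            f"composition Wald chi2(2) = {wald.statistic:.3f}   p = {wald.pvalue:.4g}",
            "",
            f"{'term':<10}{'coef':>12}{'se':>12}{'p':>12}",
        ]
        for name in PARAM_NAMES:
            lines.append(
                f"{name:<10}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}{self.pvalues[name]:>12.4g}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class SingleBehaviourFit:
    """Naive one-behaviour regression (standardized by default), for comparison."""

    outcome: str
    behaviour: str
    coef: float
    ci95: tuple
    pvalue: float
    rsquared: float
    nobs: int
    standardized: bool


def fit_single_behaviour_regression(outcome, behaviour_minutes, covariates, *,
                                    outcome_name: str = "outcome",
                                    behaviour_name: str = "behaviour",
                                    standardized: bool = True) -> SingleBehaviourFit:
    """Regress the outcome on a single behaviour's minutes plus covariates.

    With ``standardized=True`` both outcome and behaviour are scaled to
    unit variance first, so the coefficient is comparable across
    behaviours; covariates stay on their native scales.  This is the
    deliberately naive per-behaviour analysis that ignores the closed
    nature of the day — it exists to contrast with the compositional fit.
    """
    y = np.asarray(outcome, float)
    x = np.asarray(behaviour_minutes, float)
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates[list(COVARIATES)].to_numpy(float)
    cov = np.asarray(covariates, float)
    if np.std(x, ddof=1) == 0:
        raise ValueError(f"behaviour {behaviour_name!r} has zero variance")
    if standardized:
        y = (y - y.mean()) / y.std(ddof=1)
        x = (x - x.mean()) / x.std(ddof=1)
    design = np.column_stack([np.ones(len(y)), x, cov])
    res = sm.OLS(y, design).fit()
    lo, hi = res.conf_int()[1]
    return SingleBehaviourFit(
        outcome=outcome_name,
        behaviour=behaviour_name,
        coef=float(res.params[1]),
        ci95=(float(lo), float(hi)),
        pvalue=float(res.pvalues[1]),
        rsquared=float(res.rsquared),
        nobs=int(res.nobs),
        standardized=standardized,
    )
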