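"""Negative-binomial regression of contact degree and total contact hours.

The model is the standard NB2 log-link regression used for over-dispersed
contact counts:

    y_p ~ NB(mu_p, alpha),   log mu_p = x_p' beta,   Var(y) = mu + alpha mu^2

fitted by maximum likelihood jointly in (beta, alpha). Survey raking weights
enter the likelihood as frequency-style analytic weights. The inner
beta-step is iteratively reweighted least squares (a GLM fit at fixed
dispersion); the outer step profiles the dispersion by one-dimensional ML,
as in the classical glm.nb alternation.

Exponentiated coefficients are *relative rates* against each covariate's
reference level (e.g. rural vs urban residence), with Wald 95% intervals.
Per-term significance comes from likelihood-ratio tests (full model vs the
model with the term removed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy import stats

from .descriptives import duration_midpoint_minutes, participant_summaries
from .raking import WeightVector
from .schemes import REGRESSION_SCHEME
from .survey import Survey

__all__ = ["ContactRateModel", "NBRegressionResults", "fit_nb_model", "term_anova"]

#: covariate -> (reference level, is_continuous)
_COVARIATE_INFO = {
    "residence": ("urban", False),
    "day_type": ("weekday", False),
    "sex": ("male", False),
    "household_size": (None, True),
    "n_rooms": ("1", False),
    "age_band": ("0-4", False),
    "occupation": ("child_at_home", False),
}

DEFAULT_COVARIATES = tuple(_COVARIATE_INFO)


def _design_frame(survey: Survey, covariates) -> pd.DataFrame:
    pdf = survey.participants
    out = pd.DataFrame(index=pdf.index)
    for cov in covariates:
        if cov == "age_band":
            bands = REGRESSION_SCHEME.bands_of(pdf["age"].to_numpy())
            out[cov] = [REGRESSION_SCHEME.labels[b] for b in bands]
        elif cov == "day_type":
            out[cov] = pdf["diary_day_type"].to_numpy()
        elif cov == "household_size":
            out[cov] = pdf["household_size"].to_numpy(dtype=float)
        elif cov in pdf.columns:
            out[cov] = pdf[cov].to_numpy()
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return out


def _response(survey: Survey, response: str) -> np.ndarray:
    summ = participant_summaries(survey)
    if response == "degree_total":
        return summ["degree_total"].to_numpy(dtype=float)
    if response == "contact_hours":
        # total diary minutes rounded to integer counts, NB-modelled on the
        # minutes scale (relative rates are scale-free)
        cdf = survey.diary_contacts
        idx = pd.Index(summ["participant_id"])
        mins = pd.Series(0.0, index=idx)
        if len(cdf):
            per = cdf["duration_cat"].map(duration_midpoint_minutes)
            mins = mins.add(
                per.groupby(cdf["participant_id"]).sum(), fill_value=0.0
            ).reindex(idx)
        return np.round(mins.to_numpy(dtype=float))
    raise ValueError(f"unknown response {response!r}")


def _nb2_loglike(y: np.ndarray, mu: np.ndarray, alpha: float, w: np.ndarray) -> float:
    r = 1.0 / alpha
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return float(np.sum(w * ll))


class ContactRateModel:
    """Multivariable NB regression model for a contact-survey response.

    Build with :meth:`from_survey`, then :meth:`fit`. ``response`` is
    ``'degree_total'`` (diary + supplementary contacts) or
    ``'contact_hours'`` (diary duration-midpoint minutes).
    """

    def __init__(
        self,
        y: np.ndarray,
        frame: pd.DataFrame,
        weights: np.ndarray,
        response: str,
        covariates: tuple[str, ...],
    ):
        self.y = np.asarray(y, dtype=float)
        self.frame = frame
        self.weights = np.asarray(weights, dtype=float)
        self.response = response
        self.covariates = tuple(covariates)
        self._check_levels()
        self.formula = self._build_formula(self.covariates)

    @classmethod
    def from_survey(
        cls,
        survey: Survey,
        weights=None,
        response: str = "degree_total",
        covariates=DEFAULT_COVARIATES,
    ) -> "ContactRateModel":
        if isinstance(weights, WeightVector):
            w = weights.weights
        elif weights is None:
            w = np.ones(survey.n_participants)
        else:
            w = np.asarray(weights, dtype=float)
        y = _response(survey, response)
        frame = _design_frame(survey, covariates)
        return cls(y, frame, w, response, tuple(covariates))

    def _check_levels(self) -> None:
        for cov in self.covariates:
            ref, cont = _COVARIATE_INFO.get(cov, (None, False))
            if cont:
                continue
            counts = self.frame[cov].value_counts()
            empty = [lvl for lvl, n in counts.items() if n == 0]
            if empty:
                raise ValueError(f"covariate {cov} has empty level(s) {empty}")
            if len(counts) < 2:
                raise ValueError(
                    f"covariate {cov} is degenerate: single level "
                    f"{counts.index[0]!r}"
                )

    @staticmethod
    def _build_formula(covariates) -> str:
        terms = []
        for cov in covariates:
            ref, cont = _COVARIATE_INFO.get(cov, (None, False))
            if cont:
                terms.append(cov)
            elif ref is not None:
                terms.append(f"C({cov}, Treatment('{ref}'))")
            else:
                terms.append(f"C({cov})")
        return "y ~ " + " + ".join(terms) if terms else "y ~ 1"

    def _glm(self, formula: str, alpha: float):
        data = self.frame.assign(y=self.y)
        return sm.GLM.from_formula(
            formula,
            data=data,
            family=sm.families.NegativeBinomial(alpha=alpha),
            freq_weights=self.weights,
        )

    def _fit_formula(
        self, formula: str, max_outer: int = 50, tol: float = 1e-8
    ) -> tuple[object, float, float, int, bool]:
        """Alternate GLM (beta | alpha) and scalar ML (alpha | mu)."""
        alpha = 0.5
        res = None
        converged = False
        it = 0
        for it in range(1, max_outer + 1):
            res = self._glm(formula, alpha).fit()
            mu = np.asarray(res.fittedvalues, dtype=float)

            def nll(log_a: float) -> float:
                return -_nb2_loglike(self.y, mu, np.exp(log_a), self.weights)

            opt = minimize_scalar(nll, bounds=(-12.0, 8.0), method="bounded")
            new_alpha = float(np.exp(opt.x))
            if abs(new_alpha - alpha) < tol * (1.0 + alpha):
                alpha = new_alpha
                converged = True
                break
            alpha = new_alpha
        res = self._glm(formula, alpha).fit()
        llf = _nb2_loglike(
            self.y, np.asarray(res.fittedvalues, float), alpha, self.weights
        )
        return res, alpha, llf, it, converged

    def fit(self) -> "NBRegressionResults":
        res, alpha, llf, iters, converged = self._fit_formula(self.formula)
        if not converged:
            raise RuntimeError(
                "dispersion estimation did not converge "
                f"(last alpha={alpha:.4g}, {iters} outer iterations)"
            )
        return NBRegressionResults(self, res, alpha, llf)


@dataclass
class NBRegressionResults:
    """Fitted NB regression: coefficients, relative rates, dispersion, and
    per-term likelihood-ratio ANOVA."""

    model: ContactRateModel
    glm_results: object
    dispersion: float
    loglik: float

    @property
    def params(self) -> pd.Series:
        return self.glm_results.params

    @property
    def bse(self) -> pd.Series:
        return self.glm_results.bse

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        return self.glm_results.conf_int(alpha=1 - level)

    def relative_rates(self) -> pd.DataFrame:
        """Exponentiated coefficients with Wald 95% CIs, one row per
        non-reference covariate level (plus intercept), reference rows with
        rate fixed at 1."""
        ci = self.conf_int()
        rows = []
        for name, coef in self.params.items():
            lo, hi = ci.loc[name]
            variable, level = _parse_term(name)
            rows.append(
                {
                    "variable": variable,
                    "level": level,
                    "rate": float(np.exp(coef)),
                    "ci_low": float(np.exp(lo)),
                    "ci_high": float(np.exp(hi)),
                    "reference": False,
                }
            )
        for cov in self.model.covariates:
            ref, cont = _COVARIATE_INFO.get(cov, (None, False))
            if not cont and ref is not None:
                rows.append(
                    {
                        "variable": cov,
                        "level": ref,
                        "rate": 1.0,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "reference": True,
                    }
                )
        return pd.DataFrame(rows)

    def anova(self) -> pd.DataFrame:
        """Per-term likelihood-ratio tests: full model vs the model with the
        term removed. df = levels - 1 for categorical terms, 1 for
        continuous. Non-convergent reduced fits are flagged, not fabricated."""
        rows = []
        for cov in self.model.covariates:
            others = [c for c in self.model.covariates if c != cov]
            reduced_formula = self.model._build_formula(others)
            ref, cont = _COVARIATE_INFO.get(cov, (None, False))
            df = 1 if cont else self.model.frame[cov].nunique() - 1
            try:
                _, _, llf_red, _, conv = self.model._fit_formula(reduced_formula)
            except Exception:
                conv = False
                llf_red = np.nan
            if not conv:
                rows.append(
                    {"term": cov, "lr_stat": np.nan, "df": df, "p": np.nan,
                     "converged": False}
                )
                continue
            lr = max(0.0, 2.0 * (self.loglik - llf_red))
            rows.append(
                {
                    "term": cov,
                    "lr_stat": lr,
                    "df": df,
                    "p": float(stats.chi2.sf(lr, df)),
                    "converged": True,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        rr = self.relative_rates()
        lines = [
            f"Negative binomial regression — response: {self.model.response}",
            f"n = {len(self.model.y)}, dispersion alpha = {self.dispersion:.4f}, "
            f"log-likelihood = {self.loglik:.2f}",
            "",
            f"{'variable':<16}{'level':<18}{'rate':>8}  {'95% CI':>18}",
        ]
        for _, r in rr.iterrows():
            if r["reference"]:
                ci = "REF"
            else:
                ci = f"({r['ci_low']:.2f}-{r['ci_high']:.2f})"
            lines.append(
                f"{r['variable']:<16}{str(r['level']):<18}{r['rate']:>8.2f}  {ci:>18}"
            )
        return "\n".join(lines)


def _parse_term(name: str) -> tuple[str, str]:
    if name == "Intercept":
        return "intercept", ""
    if name.startswith("C("):
        inner = name[2:]
        var = inner.split(",")[0].strip()
        level = name.split("[T.")[-1].rstrip("]") if "[T." in name else ""
        return var, level
    return name, ""


# -- functional wrappers matching the operation surface ----------------------


def fit_nb_model(
    survey: Survey,
    weights=None,
    response: str = "degree_total",
    covariates=DEFAULT_COVARIATES,
) -> NBRegressionResults:
    return ContactRateModel.from_survey(survey, weights, response, covariates).fit()


def term_anova(fit: NBRegressionResults) -> pd.DataFrame:
    return fit.anova()
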