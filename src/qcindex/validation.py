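"""External validation of the care-quality score.

Mirrors the validation design used for composite care indices: regress
the score on health-system covariates (inpatient and outpatient
utilisation, cause-specific death, prevalence, risk-attributable death)
with a per-country random intercept, then correlate the model's
predictions with an independent healthcare access-and-quality reference
series. On synthetic worlds the reference is built from the latent
quality, so the correlation has a known benchmark.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
import statsmodels.api as sm

from .errors import ContractError, QCIndexError

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("inpatient_util", "outpatient_util", "cause_death",
                      "cause_prevalence", "risk_death")


class ConvergenceError(QCIndexError, RuntimeError):
    """The mixed-model optimiser failed to converge."""


@dataclass
class ValidationDesign:
    """Panel for the random-intercept validation fit.

    ``data`` holds one row per country-year with the response column,
    covariate columns, a country identifier and (optionally) the
    reference index column.
    """

    data: pd.DataFrame
    response: str = "qci"
    covariates: tuple = DEFAULT_COVARIATES
    group: str = "location"
    reference: str | None = "reference_index"

    def complete_cases(self) -> pd.DataFrame:
        cols = [self.response, *self.covariates, self.group]
        return self.data.dropna(subset=cols)


@dataclass
class ValidationResult:
    fixed_coefficients: pd.Series
    standard_errors: pd.Series
    random_intercept_variance: float
    residual_variance: float
    predicted: pd.Series
    converged: bool
    pearson_r: float | None = None
    n_obs: int = 0
    n_groups: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fixed_coefficients": self.fixed_coefficients.to_dict(),
            "standard_errors": self.standard_errors.to_dict(),
            "random_intercept_variance": self.random_intercept_variance,
            "residual_variance": self.residual_variance,
            "pearson_r": self.pearson_r,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "notes": self.notes,
        }


class RandomInterceptModel(BaseEstimator, RegressorMixin):
    """Linear mixed model with fixed covariate slopes and a per-group
    random intercept, fitted by maximum likelihood (statsmodels MixedLM).

    Attributes (after ``fit``): ``fe_params_`` (incl. intercept),
    ``bse_``, ``re_var_`` (random-intercept variance), ``resid_var_``,
    ``random_effects_`` (posterior group intercepts), ``converged_``.
    """

    def __init__(self, reml: bool = False):
        self.reml = reml

    def fit(self, X: pd.DataFrame, y, groups) -> "RandomInterceptModel":
        X = pd.DataFrame(X).astype(float)
        y = np.asarray(y, dtype=float)
        groups = pd.Series(np.asarray(groups), name="group")
        if len(X) != len(y) or len(groups) != len(y):
            raise ContractError("X, y and groups must be equally long")
        sizes = groups.value_counts()
        if (sizes >= 2).sum() < 2:
            raise ContractError(
                "need >= 2 groups with >= 2 observations each")
        exog = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(exog.to_numpy())
        if rank < exog.shape[1]:
            corr = X.corr().abs()
            np.fill_diagonal(corr.values, 0.0)
            pairs = [tuple(sorted((a, b)))
                     for a in corr.index for b in corr.columns
                     if corr.loc[a, b] > 0.999]
            raise ContractError(
                f"singular design (rank {rank} < {exog.shape[1]}); "
                f"collinear covariate pairs: {sorted(set(pairs))}")
        self.feature_names_ = list(X.columns)

        # a (near-)perfect linear fit makes the ML likelihood unbounded;
        # fall back to the exact OLS solution with zero random effects
        ols = sm.OLS(y, exog).fit()
        if ols.ssr <= 1e-10 * max(float(np.var(y)) * len(y), 1e-30):
            self.result_ = ols
            self.fe_params_ = ols.params
            self.bse_ = ols.bse
            self.re_var_ = 0.0
            self.resid_var_ = float(ols.ssr / len(y))
            self.random_effects_ = {g: 0.0 for g in groups.unique()}
            self.converged_ = True
            return self

        model = sm.MixedLM(y, exog, groups=groups)
        res = None
        last_exc: Exception | None = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cand = model.fit(reml=self.reml, method=method,
                                     maxiter=1000)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if cand.converged:
                res = cand
                break
        if res is None:
            raise ConvergenceError(
                f"mixed-model optimiser did not converge ({last_exc})")
        self.result_ = res
        self.fe_params_ = res.fe_params
        self.bse_ = res.bse_fe
        self.re_var_ = float(np.asarray(res.cov_re).ravel()[0])
        self.resid_var_ = float(res.scale)
        self.random_effects_ = {g: float(np.asarray(v).ravel()[0])
                                for g, v in res.random_effects.items()}
        self.converged_ = bool(res.converged)
        return self

    def predict(self, X: pd.DataFrame, groups=None) -> np.ndarray:
        """Fixed-effect prediction plus the posterior intercept of each
        known group (unknown groups get the population intercept)."""
        check_is_fitted(self, "fe_params_")
        X = pd.DataFrame(X).astype(float)[self.feature_names_]
        exog = sm.add_constant(X, has_constant="add")
        pred = exog.to_numpy() @ self.fe_params_.to_numpy()
        if groups is not None:
            offsets = np.array([self.random_effects_.get(g, 0.0)
                                for g in np.asarray(groups)])
            pred = pred + offsets
        return pred


def fit_random_intercept(design: ValidationDesign) -> ValidationResult:
    """Fit the validation regression and, when a reference series is
    present, correlate the predictions with it."""
    df = design.complete_cases()
    dropped = len(design.data) - len(df)
    notes = []
    if dropped:
        notes.append(f"{dropped} incomplete row(s) excluded")
    model = RandomInterceptModel().fit(df[list(design.covariates)],
                                       df[design.response],
                                       df[design.group])
    pred = pd.Series(model.predict(df[list(design.covariates)],
                                   groups=df[design.group]),
                     index=df.index, name="predicted")
    r = None
    if design.reference and design.reference in df.columns:
        r = correlate_with_reference(pred, df[design.reference])
    return ValidationResult(
        fixed_coefficients=model.fe_params_,
        standard_errors=model.bse_,
        random_intercept_variance=model.re_var_,
        residual_variance=model.resid_var_,
        predicted=pred,
        converged=model.converged_,
        pearson_r=r,
        n_obs=len(df),
        n_groups=df[design.group].nunique(),
        notes=notes,
    )


def correlate_with_reference(predicted: pd.Series,
                             reference: pd.Series) -> float:
    """Pearson correlation on the key intersection of two keyed series."""
    p = pd.Series(predicted).dropna()
    q = pd.Series(reference).dropna()
    shared = p.index.intersection(q.index)
    dropped = max(len(p), len(q)) - len(shared)
    if dropped:
        logger.warning("%d key(s) outside the intersection dropped",
                       dropped)
    if len(shared) < 3:
        raise ContractError("need >= 3 shared keys for a correlation")
    a, b = p.loc[shared], q.loc[shared]
    if float(a.std(ddof=0)) == 0 or float(b.std(ddof=0)) == 0:
        raise ContractError("zero variance in one of the series")
    return float(stats.pearsonr(a, b)[0])
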