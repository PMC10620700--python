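"""Two-group statistics: pooled t-tests, chi-squared, logistic odds ratios,
and covariate-adjusted Pearson correlations.

Conventions, fixed across the package:

* Student's pooled-variance t with ``df = n1 + n2 - 2`` and the sign
  ``t = (CN - MCI) / SE``; two-sided p-values.
* Pearson chi-squared without continuity correction, df = 1, for 2x2 tables.
* Logistic regression by maximum likelihood (Newton), predictor z-scored over
  the analysis sample before fitting so odds ratios are per SD; Wald 95% CI.
* Partial correlation by least-squares residualization on covariates plus an
  intercept, with ``t = r * sqrt((n - 2 - k) / (1 - r^2))`` on ``n - 2 - k``
  degrees of freedom.
* Significance stars: ``***`` p < 0.001, ``**`` p < 0.01, ``*`` p <= 0.05,
  ``ns`` otherwise; no multiplicity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import FitError, RankError, StructuralError

DEFAULT_ALPHA = 0.05

#: Covariates of the adjusted models, in design order.
DEMOGRAPHIC_COVARIATES = ("age_years", "sex_male", "education_years")


def star(p: float, alpha: float = DEFAULT_ALPHA) -> str:
    """Significance star code (``***``/``**``/``*``/``ns``)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= alpha:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    p: float
    df: int
    infinite: bool = False  # zero pooled variance with unequal means


def students_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> TTestResult:
    """Pooled-variance two-sample t from group summaries (group1 = CN)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    diff = mean1 - mean2
    if pooled_var == 0.0:
        if diff == 0.0:
            return TTestResult(mean1, sd1, n1, mean2, sd2, n2, 0.0, 1.0, df)
        t = math.inf if diff > 0 else -math.inf
        return TTestResult(mean1, sd1, n1, mean2, sd2, n2, t, 0.0, df, infinite=True)
    se = math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(mean1, sd1, n1, mean2, sd2, n2, t, p, df)


def students_t(group1, group2) -> TTestResult:
    """Pooled-variance t from raw samples; delegates to the summary form."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    return students_t_from_summary(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y),
    )


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

@dataclass
class ChiSquaredResult:
    statistic: float
    p: float
    df: int


def chi_squared(table) -> ChiSquaredResult:
    """Pearson chi-squared (no continuity correction) for a 2x2 table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise StructuralError("contingency table must be 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined with a zero margin")
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return ChiSquaredResult(float(stat), float(p), int(dof))


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticModelResult:
    model_id: int
    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    coef: float
    se: float
    covariates: tuple[str, ...] = ()
    nobs: int = 0

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("odds ratio must lie inside its confidence interval")


def fit_logistic(
    outcome,
    predictor,
    covariates: pd.DataFrame | np.ndarray | None = None,
    *,
    standardize: bool = True,
    model_id: int = 1,
    predictor_name: str = "x",
    alpha: float = DEFAULT_ALPHA,
) -> LogisticModelResult:
    """Logistic regression of a binary outcome on one predictor (+ covariates).

    The predictor is z-scored over the analysis sample before fitting when
    ``standardize`` (the default), so the odds ratio is per SD of the
    predictor.  Wald CI and p-value for the predictor coefficient; Newton
    optimizer, log-likelihood tolerance 1e-8, at most 100 iterations.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) != 2:
        raise ValueError("outcome must be binary with both classes present")

    sd = x.std(ddof=1)
    if sd == 0:
        raise RankError("predictor is constant")
    xs = (x - x.mean()) / sd if standardize else x

    cols = [np.ones_like(xs), xs]
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        cov_names = tuple(str(c) for c in cov.columns)
        cols.extend(np.asarray(cov[c], dtype=float) for c in cov.columns)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankError("design matrix is rank deficient")

    try:
        res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge within 100 iterations")

    b = float(res.params[1])
    se = float(res.bse[1])
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    return LogisticModelResult(
        model_id=model_id,
        predictor=predictor_name,
        odds_ratio=math.exp(b),
        ci_low=math.exp(b - z * se),
        ci_high=math.exp(b + z * se),
        p_value=float(res.pvalues[1]),
        coef=b,
        se=se,
        covariates=cov_names,
        nobs=int(res.nobs),
    )


def nested_models(
    data: pd.DataFrame,
    feature: str,
    *,
    outcome_col: str = "mci",
    standardize: bool = True,
) -> dict[int, LogisticModelResult]:
    """The three nested logistic models for one feature.

    Model 1: feature only.  Model 2: + age, sex (female=0/male=1), education.
    Model 3: + MMSE.  ``data`` must carry the outcome indicator column
    (CN=0/MCI=1) plus ``age_years``, ``sex_male``, ``education_years``,
    ``mmse`` and the feature.
    """
    covsets = {
        1: (),
        2: DEMOGRAPHIC_COVARIATES,
        3: DEMOGRAPHIC_COVARIATES + ("mmse",),
    }
    out = {}
    for mid, covs in covsets.items():
        out[mid] = fit_logistic(
            data[outcome_col], data[feature],
            covariates=data[list(covs)] if covs else None,
            standardize=standardize, model_id=mid, predictor_name=feature,
        )
    return out


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrelationResult:
    r: float
    p: float
    n: int
    n_covariates: int
    covariates: tuple[str, ...] = field(default_factory=tuple)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x, y, covariates=None, covariate_names: tuple[str, ...] = ()
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after removing covariates by least
    squares (intercept always included)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise StructuralError("x and y must have equal length")
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(pd.DataFrame(covariates), dtype=float)
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankError("covariates are collinear")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    # a variable fully explained by the covariates has nothing left to
    # correlate: r is 0 by convention (guards the exact-partialling case)
    ssx, ssy = float(rx @ rx), float(ry @ ry)
    varx = float(((x - x.mean()) ** 2).sum())
    vary = float(((y - y.mean()) ** 2).sum())
    if ssx <= 1e-24 * max(varx, 1.0) or ssy <= 1e-24 * max(vary, 1.0):
        return PartialCorrelationResult(r=0.0, p=1.0, n=n, n_covariates=k,
                                        covariates=tuple(covariate_names))
    r = float(rx @ ry) / math.sqrt(ssx * ssy)
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return PartialCorrelationResult(r=r, p=p, n=n, n_covariates=k,
                                    covariates=tuple(covariate_names))


def partial_correlation_from_matrix(data: np.ndarray) -> float:
    """Partial correlation of columns 0 and 1 of ``data`` given the rest, via
    the inverse-correlation-matrix identity (independent cross-check route)."""
    corr = np.corrcoef(np.asarray(data, dtype=float), rowvar=False)
    prec = np.linalg.inv(corr)
    return float(-prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1]))
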