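"""Gaussian GLMs and AIC model comparison for the microcosm analysis.

Two questions are addressed statistically.  First, how do resource level,
initial density and their interaction shape per-capita growth (a Gaussian
GLM with identity link, i.e. ordinary least squares, with per-term F
tests)?  Second, is the per-microcosm interference exponent explained by
initial density alone (null model) or by density plus resource
availability (saturated model)?  The two are compared by AIC with the
conventional rule that models closer than two AIC units are
indistinguishable.

AIC uses the full Gaussian likelihood convention
``AIC = n ln(RSS/n) + n (1 + ln 2pi) + 2k`` with ``k`` counting the mean
parameters plus one for the residual standard deviation, applied
consistently across the inference and GLM layers so that AIC differences
are internally comparable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import DegenerateDesignError, DomainError, InsufficientDataError

__all__ = [
    "GLMResult",
    "ModelComparison",
    "aic_gaussian",
    "fit_gaussian_glm",
    "growth_glm",
    "m_model_comparison",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GLMResult:
    """Summary of one Gaussian GLM (OLS) fit.

    ``f_stats``/``f_dfs``/``p_values`` are per-term Type-II F statistics
    (main effects adjusted for each other, the interaction tested against
    the full model's residual).
    """

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    f_stats: dict[str, float]
    f_dfs: dict[str, int]
    p_values: dict[str, float]
    aic: float
    adj_r2: float
    n: int
    rss: float
    formula: str


@dataclass(frozen=True)
class ModelComparison:
    """AIC comparison of two candidate models under the delta-AIC > 2 rule."""

    model_labels: tuple[str, str]
    aics: tuple[float, float]
    delta_aic: float
    distinguishable: bool
    best_model: str


def aic_gaussian(rss: float, n: int, k: int) -> float:
    """AIC of a Gaussian model with MLE variance ``RSS/n``.

    ``k`` counts mean parameters plus one for sigma.  ``RSS = 0`` (a
    perfect fit) returns negative infinity with a warning, since the
    profile likelihood is unbounded there.
    """
    if n <= 0 or k < 1:
        raise DomainError("need n > 0 and k >= 1")
    if rss < 0:
        raise DomainError("RSS must be nonnegative")
    if rss == 0:
        warnings.warn("AIC is -inf for a perfect (RSS = 0) fit", stacklevel=2)
        return float("-inf")
    return n * math.log(rss / n) + n * (1.0 + math.log(2.0 * math.pi)) + 2.0 * k


def fit_gaussian_glm(table: pd.DataFrame, response: str, terms: str) -> GLMResult:
    """Ordinary-least-squares fit of ``response ~ terms`` with Type-II F tests.

    ``terms`` is a patsy right-hand-side formula (e.g.
    ``"C(resource_mg) * initial_density"``).  Raises
    :class:`DegenerateDesignError` on a rank-deficient design.
    """
    if response not in table.columns:
        raise DomainError(f"response column {response!r} missing")
    formula = f"{response} ~ {terms}"
    model = smf.ols(formula, data=table)
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise InsufficientDataError("need more observations than parameters")
    res = model.fit()
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise DegenerateDesignError(f"rank-deficient design for formula {formula!r}")
    k_mean = model.exog.shape[1]
    n = int(res.nobs)
    aic = aic_gaussian(float(res.ssr), n, k_mean + 1)
    if k_mean > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova = anova_lm(res, typ=2)
        anova = anova.drop(index="Residual", errors="ignore")
        f_stats = {t: float(anova.loc[t, "F"]) for t in anova.index}
        f_dfs = {t: int(anova.loc[t, "df"]) for t in anova.index}
        p_values = {t: float(anova.loc[t, "PR(>F)"]) for t in anova.index}
        term_names = tuple(anova.index)
    else:  # intercept-only model has no testable terms
        f_stats, f_dfs, p_values, term_names = {}, {}, {}, ()
    return GLMResult(
        terms=term_names,
        coefficients={name: float(v) for name, v in res.params.items()},
        f_stats=f_stats,
        f_dfs=f_dfs,
        p_values=p_values,
        aic=aic,
        adj_r2=float(res.rsquared_adj),
        n=n,
        rss=float(res.ssr),
        formula=formula,
    )


def growth_glm(growth_table: pd.DataFrame) -> GLMResult:
    """Per-capita growth as a function of resource, density and interaction.

    Resource enters as a two-level factor and initial density as a
    continuous covariate; only valid records (positive initial and final
    densities) are used.  A subadditive system — the resource effect
    shrinking as density grows — shows up as a negative
    resource-by-density interaction coefficient.
    """
    tab = growth_table
    if "valid" in tab.columns:
        tab = tab[tab["valid"]]
    if tab["resource_mg"].nunique() < 2:
        raise DegenerateDesignError("growth GLM needs both resource levels")
    if tab["initial_density"].nunique() < 2:
        raise DegenerateDesignError("growth GLM needs >= 2 distinct densities")
    return fit_gaussian_glm(
        tab, "per_capita_growth", "C(resource_mg) * initial_density"
    )


def m_model_comparison(
    m_table: pd.DataFrame,
) -> tuple[GLMResult, GLMResult, ModelComparison]:
    """Density-only (null) vs density-plus-resource (saturated) models for m.

    Fits ``m_hat ~ initial_density`` and
    ``m_hat ~ initial_density + C(resource_mg)`` on the feasible
    per-microcosm estimates and compares them by AIC under the
    delta-AIC > 2 rule.
    """
    tab = m_table
    if "feasible" in tab.columns:
        tab = tab[tab["feasible"]]
    tab = tab.dropna(subset=["m_hat"])
    if len(tab) < 3:
        raise InsufficientDataError("need >= 3 feasible per-microcosm m estimates")
    if tab["initial_density"].nunique() < 2:
        raise DegenerateDesignError("m models need >= 2 distinct densities")
    null = fit_gaussian_glm(tab, "m_hat", "initial_density")
    saturated = fit_gaussian_glm(tab, "m_hat", "initial_density + C(resource_mg)")
    delta = abs(null.aic - saturated.aic)
    best = "null" if null.aic <= saturated.aic else "saturated"
    comparison = ModelComparison(
        model_labels=("null", "saturated"),
        aics=(null.aic, saturated.aic),
        delta_aic=delta,
        distinguishable=delta > 2.0,
        best_model=best,
    )
    return null, saturated, comparison
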