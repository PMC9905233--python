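"""Analysis models for simulator and session output.

The substantive quantities live in :mod:`cohesim.bandit_sim` and
:mod:`cohesim.behavior_metrics`; this module reproduces the surrounding
statistical analyses on their output:

* a Poisson mixed model for how many agents choose the profitable option per
  iteration, with bonus scheme entered through sum-to-zero (deviation)
  contrasts and a per-run random intercept;
* a logistic mixed model for the per-round probability of choosing the
  profitable option (learning curve), optionally with a condition contrast;
* linear mixed models relating decision quality (choice score) to exploration
  length (half-change round) with a quadratic term, plus the likelihood-ratio
  comparison against the linear-only model;
* a product-of-coefficients mediation analysis with percentile-bootstrap
  confidence intervals;
* thin wrappers around the standard two-group tests (Welch t, rank-sum with
  continuity correction, chi-square).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import EmptyInputError
from .glmm import GLMMFit, RandomTerm, fit_glmm

__all__ = [
    "ModelResult",
    "MediationResult",
    "CompareResult",
    "BONUS_KIND_LEVELS",
    "fit_profitable_count_model",
    "fit_learning_curve",
    "fit_exploration_quality",
    "mediate",
    "compare_groups",
]

#: Fixed level order of the bonus-scheme factor for deviation coding.
BONUS_KIND_LEVELS = ("none", "additive", "multiplicative")


@dataclass
class ModelResult:
    """Unified regression summary: unstandardized coefficients on the model's
    link scale, Wald 95% CIs, p-values, and fit statistics (conditional and
    marginal pseudo-R², log-likelihood, variance components)."""

    coefficients: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    fit_stats: dict[str, float] = field(default_factory=dict)
    model: str = ""

    def __post_init__(self):
        for name, est in self.coefficients.items():
            lo, hi = self.ci95.get(name, (-np.inf, np.inf))
            if not (lo <= est <= hi):
                raise ValueError(f"CI of {name!r} does not bracket the estimate")


@dataclass
class MediationResult:
    """Product-of-coefficients mediation decomposition with bootstrap CIs.

    ``proportion_mediated`` is reported as 0 whenever the indirect-effect CI
    spans zero, matching the convention of reporting a null mediation as
    "proportion mediated = 0"."""

    total_effect: float
    direct_effect: float
    indirect_effect: float
    total_ci: tuple[float, float]
    direct_ci: tuple[float, float]
    indirect_ci: tuple[float, float]
    proportion_mediated: float
    n_boot: int


@dataclass
class CompareResult:
    statistic: float
    p_value: float
    effect_size: float
    test: str


def _deviation_columns(kinds: pd.Series) -> tuple[pd.DataFrame, list[str]]:
    """Sum-to-zero contrast columns for the bonus-kind levels present.

    Columns code all present levels but the last (in canonical order); the
    last level carries −1 on every column, so each level's deviation effect
    reads "versus the mean of all kinds".  Returns the columns and the
    ordered list of present levels."""
    unknown = set(kinds.unique()) - set(BONUS_KIND_LEVELS)
    if unknown:
        raise ValueError(f"unknown bonus kinds {sorted(unknown)}")
    present = [lev for lev in BONUS_KIND_LEVELS if (kinds == lev).any()]
    out = pd.DataFrame(index=kinds.index)
    last = present[-1]
    for lev in present[:-1]:
        out[f"bonus[{lev}]"] = np.where(kinds == lev, 1.0, np.where(kinds == last, -1.0, 0.0))
    return out, present


def _glmm_to_result(fit: GLMMFit, model: str) -> ModelResult:
    ci = fit.ci95()
    return ModelResult(
        coefficients={n: float(b) for n, b in zip(fit.fe_names, fit.fe_params)},
        ci95=ci,
        p_values={n: float(p) for n, p in zip(fit.fe_names, fit.fe_pvalues)},
        fit_stats={
            "r2_conditional": fit.r2_conditional,
            "r2_marginal": fit.r2_marginal,
            "loglik": fit.loglik,
            "n_obs": fit.n_obs,
            **{f"sd({k})": v for k, v in fit.vc_sd.items()},
        },
        model=model,
    )


def _add_derived_level(
    result: ModelResult,
    fit: GLMMFit,
    levels: Sequence[str],
    interaction_with: str | None = None,
) -> None:
    """Append the omitted deviation level's coefficient (−sum of the coded
    ones) with a delta-method CI from the fixed-effect covariance."""
    suffix = f":{interaction_with}" if interaction_with else ""
    names = [f"bonus[{lev}]{suffix}" for lev in levels[:-1]]
    idx = [fit.fe_names.index(n) for n in names]
    est = -float(np.sum(fit.fe_params[idx]))
    var = float(np.ones(len(idx)) @ fit.fe_vcov[np.ix_(idx, idx)] @ np.ones(len(idx)))
    se = np.sqrt(var)
    name = f"bonus[{levels[-1]}]{suffix}"
    result.coefficients[name] = est
    result.ci95[name] = (est - 1.96 * se, est + 1.96 * se)
    result.p_values[name] = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else np.nan


def fit_profitable_count_model(counts: pd.DataFrame) -> ModelResult:
    """Poisson mixed model for the number of agents on the profitable option.

    Expects a long table with columns ``run``, ``iteration``, ``bonus_kind``
    and integer ``count``; fits ``count ~ iteration * bonus_kind`` with
    deviation-coded bonus kinds and a random intercept grouped by the ``run``
    column exactly as logged (runs are numbered within scheme, so the same
    run number recurs across schemes, mirroring how simulation output tables
    are laid out).  The coefficient for the deviation level that the
    contrasts omit (``multiplicative``) is derived as the negative sum of the
    coded ones and reported alongside them.
    """
    required = {"run", "iteration", "bonus_kind", "count"}
    if missing := required - set(counts.columns):
        raise ValueError(f"counts table is missing columns {sorted(missing)}")
    if len(counts) == 0:
        raise EmptyInputError("empty counts table")
    y = counts["count"].to_numpy()
    if np.any(y != np.round(y)) or np.any(y < 0):
        raise ValueError("counts must be non-negative integers")

    dev, levels = _deviation_columns(counts["bonus_kind"])
    X = pd.DataFrame({"Intercept": 1.0, "iteration": counts["iteration"].to_numpy(float)})
    for col in dev.columns:
        X[col] = dev[col].to_numpy()
        X[f"{col}:iteration"] = dev[col].to_numpy() * X["iteration"].to_numpy()
    fit = fit_glmm(
        y, X, [RandomTerm.intercept("run", counts["run"])], family="poisson"
    )
    result = _glmm_to_result(fit, "poisson-glmm: count ~ iteration * bonus (deviation), (1|run)")
    if len(levels) > 1:
        _add_derived_level(result, fit, levels)
        _add_derived_level(result, fit, levels, interaction_with="iteration")
    return result


def fit_learning_curve(
    choices: pd.DataFrame,
    condition: bool = False,
    include_intercept: bool | None = None,
    re_structure: Sequence[str] = ("participant", "round|participant", "group"),
) -> ModelResult:
    """Logistic mixed model for the probability of choosing the profitable
    option over rounds.

    Expects columns ``group``, ``player``, ``round`` and binary
    ``profitable`` (plus ``condition`` coded 0/1 when ``condition=True``).
    Without a condition the fixed part is ``-1 + round`` (no intercept); with
    one it is ``condition * round`` with intercept.  Random effects default
    to intercepts for participant and group plus a per-participant random
    slope for round; drop entries from ``re_structure`` to simplify.
    """
    required = {"group", "player", "round", "profitable"}
    if missing := required - set(choices.columns):
        raise ValueError(f"choice table is missing columns {sorted(missing)}")
    y = choices["profitable"].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("profitable must be a binary 0/1 indicator")
    if include_intercept is None:
        include_intercept = condition

    rnd = choices["round"].to_numpy(float)
    cols: dict[str, np.ndarray] = {}
    if include_intercept:
        cols["Intercept"] = np.ones(len(choices))
    cols["round"] = rnd
    if condition:
        cond = choices["condition"].to_numpy(float)
        cols["condition"] = cond
        cols["condition:round"] = cond * rnd
    X = pd.DataFrame(cols)

    participant = choices["group"].astype(str) + "//" + choices["player"].astype(str)
    terms = []
    for spec in re_structure:
        if spec == "participant":
            terms.append(RandomTerm.intercept("participant", participant))
        elif spec == "group":
            terms.append(RandomTerm.intercept("group", choices["group"]))
        elif spec == "round|participant":
            terms.append(RandomTerm.slope("round|participant", participant, rnd))
        else:
            raise ValueError(f"unknown random-effect spec {spec!r}")
    fit = fit_glmm(y, X, terms, family="binomial")
    fixed = "condition * round" if condition else ("round" if include_intercept else "-1 + round")
    return _glmm_to_result(fit, f"logistic-glmm: profitable ~ {fixed}")


def fit_exploration_quality(scores: pd.DataFrame) -> ModelResult:
    """Linear mixed models of choice score on half-change round.

    Fits the quadratic model ``choice_score ~ hcr + hcr²`` and the
    linear-only model, both with a group random intercept (dropped with a
    warning when fewer than two groups are present), by maximum likelihood,
    and reports the quadratic model's coefficients together with the
    likelihood-ratio chi-square between the two model fits.
    """
    required = {"group", "choice_score", "half_change_round"}
    if missing := required - set(scores.columns):
        raise ValueError(f"scores table is missing columns {sorted(missing)}")
    df = scores.copy()
    df["hcr"] = df["half_change_round"].astype(float)
    df["hcr_sq"] = df["hcr"] ** 2

    n_groups = df["group"].nunique()
    if n_groups >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            quad = smf.mixedlm(
                "choice_score ~ hcr + hcr_sq", df, groups=df["group"]
            ).fit(reml=False)
            lin = smf.mixedlm(
                "choice_score ~ hcr", df, groups=df["group"]
            ).fit(reml=False)
        ll_quad, ll_lin = quad.llf, lin.llf
        params, bse, pvals = quad.fe_params, quad.bse_fe, quad.pvalues
        group_var = float(quad.cov_re.iloc[0, 0])
        resid_var = float(quad.scale)
    else:
        warnings.warn("fewer than 2 groups: dropping the group random effect")
        quad = smf.ols("choice_score ~ hcr + hcr_sq", df).fit()
        lin = smf.ols("choice_score ~ hcr", df).fit()
        ll_quad, ll_lin = quad.llf, lin.llf
        params, bse, pvals = quad.params, quad.bse, quad.pvalues
        group_var, resid_var = 0.0, float(quad.mse_resid)

    lrt = max(0.0, 2.0 * (ll_quad - ll_lin))
    names = {"Intercept": "Intercept", "hcr": "half_change_round",
             "hcr_sq": "half_change_round^2"}
    coeffs, ci95, pv = {}, {}, {}
    for raw, name in names.items():
        if raw not in params.index:
            continue
        est, se = float(params[raw]), float(bse[raw])
        coeffs[name] = est
        ci95[name] = (est - 1.96 * se, est + 1.96 * se)
        pv[name] = float(pvals[raw])
    var_f = float(np.var(quad.fittedvalues)) if n_groups < 2 else float(
        np.var(np.asarray(quad.model.exog @ quad.fe_params))
    )
    denom = var_f + group_var + resid_var
    return ModelResult(
        coefficients=coeffs,
        ci95=ci95,
        p_values=pv,
        fit_stats={
            "lrt_chi2": lrt,
            "lrt_p": float(stats.chi2.sf(lrt, df=1)),
            "loglik_quadratic": float(ll_quad),
            "loglik_linear": float(ll_lin),
            "linear_only_slope": float(lin.params["hcr"]),
            "r2_marginal": var_f / denom if denom > 0 else np.nan,
            "r2_conditional": (var_f + group_var) / denom if denom > 0 else np.nan,
        },
        model="lmm: choice_score ~ half_change_round + half_change_round^2, (1|group)",
    )


def _ols_coef(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def mediate(
    x: Sequence[float],
    m: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Product-of-coefficients mediation of ``x`` on ``y`` through ``m``.

    OLS paths: total = slope of ``y ~ x``; a-path = slope of ``m ~ x``;
    b-path and direct effect from ``y ~ x + m``; indirect = a·b.  For linear
    models the decomposition ``total = direct + indirect`` is exact.
    Percentile-bootstrap CIs over ``n_boot`` case resamples (at least 100).
    A binary ``y`` is handled on the linear-probability scale.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must be aligned")
    n = len(x)
    if n < 3:
        raise EmptyInputError("mediation needs at least 3 observations")

    def paths(xi, mi, yi):
        ones = np.ones_like(xi)
        total = _ols_coef(yi, np.column_stack([ones, xi]))[1]
        a = _ols_coef(mi, np.column_stack([ones, xi]))[1]
        bd = _ols_coef(yi, np.column_stack([ones, xi, mi]))
        direct, b = bd[1], bd[2]
        return total, direct, a * b

    total, direct, indirect = paths(x, m, y)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 3))
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[i] = paths(x[idx], m[idx], y[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    indirect_ci = (float(lo[2]), float(hi[2]))
    spans_zero = indirect_ci[0] <= 0.0 <= indirect_ci[1]
    prop = 0.0 if spans_zero or total == 0 else float(indirect / total)
    return MediationResult(
        total_effect=float(total),
        direct_effect=float(direct),
        indirect_effect=float(indirect),
        total_ci=(float(lo[0]), float(hi[0])),
        direct_ci=(float(lo[1]), float(hi[1])),
        indirect_ci=indirect_ci,
        proportion_mediated=prop,
        n_boot=n_boot,
    )


def compare_groups(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | None = None,
    test: str = "welch_t",
    alternative: str = "two-sided",
) -> CompareResult:
    """Two-group comparison in the reporting style of the analyses here.

    ``welch_t``: Welch two-sample t with Cohen's d; ``wilcoxon``: rank-sum
    with continuity correction and rank-biserial effect size; ``chi_square``:
    contingency-table test (pass the table as ``a``) with Cramér's V.
    """
    if test == "chi_square":
        table = np.asarray(a, float)
        if table.size == 0:
            raise EmptyInputError("empty contingency table")
        chi2, p, dof, _ = stats.chi2_contingency(table)
        n = table.sum()
        k = min(table.shape) - 1
        v = float(np.sqrt(chi2 / (n * k))) if n > 0 and k > 0 else np.nan
        return CompareResult(float(chi2), float(p), v, test)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise EmptyInputError("each group needs at least 2 observations")
    if test == "welch_t":
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        na, nb = len(a), len(b)
        pooled = np.sqrt(
            ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        )
        d = float((np.mean(a) - np.mean(b)) / pooled) if pooled > 0 else 0.0
        return CompareResult(float(t), float(p), d, test)
    if test == "wilcoxon":
        u, p = stats.mannwhitneyu(a, b, use_continuity=True, alternative=alternative)
        rb = float(2.0 * u / (len(a) * len(b)) - 1.0)  # rank-biserial
        return CompareResult(float(u), float(p), rb, test)
    raise ValueError(f"unknown test {test!r}")
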