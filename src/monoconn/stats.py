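"""Mixed-model and correlation statistics on the pair-session table.

Linear mixed models carry a random intercept for the recording animal; the
contribution of that random effect is tested with a likelihood-ratio test
against the plain linear model (naive chi-square df=1 reference, which is
conservative for a variance tested at its boundary). Independent
contributions of fixed predictors use single-term F-tests on the full ML
fit. Correlation tooling covers partial correlations by residualization,
the Fisher-Z two-correlation comparison, Mann-Whitney rank tests,
Holm-Bonferroni step-down multiplicity control, and bootstrap R² intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class ModelResult:
    """Summary of a fitted (mixed) linear model."""

    response: str
    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, stat, p
    loglike: float
    method: str  # "ML" or "REML" (or "OLS" fallback)
    n_obs: int
    n_groups: int
    converged: bool
    group_var: float = float("nan")
    model: object = field(default=None, repr=False)


def _design(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    group: str | None,
) -> pd.DataFrame:
    cols = [response, *predictors] + ([group] if group else [])
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    data = table[cols].dropna()
    dropped = len(table) - len(data)
    if dropped:
        logger.info("dropped %d rows with missing values (listwise)", dropped)
    return data


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed_predictors: list[str],
    group: str | None = "animal_id",
    method: str = "ML",
) -> ModelResult:
    """Random-intercept linear mixed model of ``response`` on the predictors.

    ML (reml=False) is the default so nested fits support likelihood-ratio
    comparisons; pass ``method="REML"`` for variance-component reporting.
    With fewer than 2 groups the model degenerates to OLS with a warning.
    """
    data = _design(table, response, fixed_predictors, group)
    X = sm.add_constant(data[fixed_predictors], has_constant="add")
    y = data[response].to_numpy(dtype=np.float64)
    n_groups = data[group].nunique() if group else 0
    if group is None or n_groups < 2:
        if group is not None:
            warnings.warn("fewer than 2 groups; falling back to OLS")
        res = sm.OLS(y, X).fit()
        fe = pd.DataFrame(
            {
                "estimate": res.params,
                "se": res.bse,
                "stat": res.tvalues,
                "p": res.pvalues,
            }
        )
        return ModelResult(response, fe, float(res.llf), "OLS",
                           int(res.nobs), 0, True, model=res)
    md = sm.MixedLM(y, X, groups=data[group].to_numpy())
    res = _robust_mixed_fit(md, reml=(method.upper() == "REML"))
    if res is None or not np.isfinite(res.llf):
        # group variance at the zero boundary (singular Hessian or infinite
        # reported likelihood): the ML solution coincides with OLS
        ols = sm.OLS(y, X).fit()
        fe = pd.DataFrame(
            {
                "estimate": ols.params,
                "se": ols.bse,
                "stat": ols.tvalues,
                "p": ols.pvalues,
            }
        )
        return ModelResult(response, fe, float(ols.llf), "OLS",
                           int(ols.nobs), int(n_groups), True,
                           group_var=0.0, model=ols)
    k = X.shape[1]
    fe = pd.DataFrame(
        {
            "estimate": res.params[:k],
            "se": res.bse[:k],
            "stat": res.tvalues[:k],
            "p": res.pvalues[:k],
        },
        index=X.columns,
    )
    return ModelResult(
        response,
        fe,
        float(res.llf),
        method.upper(),
        int(res.nobs),
        int(n_groups),
        bool(res.converged),
        group_var=float(np.asarray(res.cov_re).ravel()[0]),
        model=res,
    )


def _robust_mixed_fit(md, reml: bool):
    """Fit a MixedLM, falling back across optimizers.

    An optimizer that errors out or reports a non-finite likelihood (the
    variance collapsed to the boundary numerically) is skipped; ``None``
    means every attempt failed and the caller should use the OLS boundary
    solution.
    """
    for opt in ("bfgs", "powell", "cg"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = md.fit(reml=reml, method=opt)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if np.isfinite(res.llf):
            return res
    return None


def lrt_random_effect(
    table: pd.DataFrame,
    response: str,
    fixed_predictors: list[str],
    group: str = "animal_id",
) -> tuple[float, float]:
    """Likelihood-ratio test for the animal random intercept.

    Compares the ML mixed fit against the plain linear model on the same
    rows: ``stat = 2 * (llf_mixed - llf_ols)``, p from chi-square df=1
    (conservative at the variance boundary). Negative stats from optimizer
    slack are clipped to 0.
    """
    data = _design(table, response, fixed_predictors, group)
    mixed = fit_lmm(data, response, fixed_predictors, group=group, method="ML")
    X = sm.add_constant(data[fixed_predictors], has_constant="add")
    ols = sm.OLS(data[response].to_numpy(dtype=np.float64), X).fit()
    stat = max(0.0, 2.0 * (mixed.loglike - float(ols.llf)))
    p = float(sps.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p


def model_comparison(
    table: pd.DataFrame,
    response: str,
    candidate_predictors: list[str],
    group: str | None = "animal_id",
) -> pd.DataFrame:
    """Independent contribution of each predictor given all the others.

    Fits the full model once and tests each predictor's coefficient with a
    single-term F-test (equivalent to comparing against the model dropping
    that term, on the same rows). Returns a frame indexed by predictor with
    columns estimate, F, p. Collinear predictors trigger a warning.
    """
    if len(candidate_predictors) < 2:
        raise ValueError("model_comparison needs at least 2 candidate predictors")
    data = _design(table, response, candidate_predictors, group)
    X = data[candidate_predictors].to_numpy(dtype=np.float64)
    cond = np.linalg.cond(np.column_stack([np.ones(len(X)), X]))
    if cond > 1e6:
        warnings.warn(f"predictors nearly collinear (condition number {cond:.2g})")
    full = fit_lmm(data, response, candidate_predictors, group=group, method="ML")
    rows = []
    for pred in candidate_predictors:
        if full.method == "OLS":
            ft = full.model.f_test(f"{pred} = 0")
            F, p = float(ft.fvalue), float(ft.pvalue)
        else:
            ft = full.model.wald_test(f"{pred} = 0", use_f=True, scalar=True)
            F, p = float(ft.statistic), float(ft.pvalue)
        rows.append((pred, float(full.fixed_effects.loc[pred, "estimate"]), F, p))
    return pd.DataFrame(rows, columns=["predictor", "estimate", "F", "p"]).set_index(
        "predictor"
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def partial_correlation(
    x: np.ndarray, y: np.ndarray, controls: np.ndarray | None = None
) -> float:
    """Partial correlation of x and y given controls, by residualization.

    Both variables are regressed (with intercept) on the controls; the
    Pearson correlation of the residuals is returned. With no controls this
    equals the plain correlation. ``nan`` when either residual is constant.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if controls is None or (np.asarray(controls).size == 0):
        C = np.ones((x.size, 1))
    else:
        C = np.column_stack([np.ones(x.size), np.asarray(controls, dtype=np.float64)])
    if x.size <= C.shape[1] + 1:
        raise ValueError("need n > number of controls + 2 observations")
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return float("nan")  # constant input: correlation undefined
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    # a variable fully explained by the controls has nothing left to
    # correlate: its partial correlation is 0 (residuals are round-off)
    if np.std(rx) < 1e-10 * sx or np.std(ry) < 1e-10 * sy:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided Z-test for the difference of two independent correlations.

    ``Z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
        if n < 4:
            raise ValueError("need n >= 4 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U rank test."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(
    pvals, alpha: float = ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down correction.

    Returns ``(reject, p_adjusted)`` in the input order. The smallest p is
    compared against ``alpha / m``, the next against ``alpha / (m-1)``, and
    the step-down stops at the first failure. Adjusted p-values are the
    running-maximum of ``(m - k) * p_(k)`` clipped at 1.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return np.empty(0, dtype=bool), np.empty(0)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, (m - k) * p[idx])
        adj[idx] = min(1.0, running)
    reject = np.zeros(m, dtype=bool)
    for k, idx in enumerate(order):
        if p[idx] <= alpha / (m - k):
            reject[idx] = True
        else:
            break
    return reject, adj


def r2_with_ci(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """OLS R² with a seeded bootstrap percentile confidence interval."""
    data = _design(table, response, predictors, group=None)
    X = sm.add_constant(data[predictors], has_constant="add").to_numpy()
    y = data[response].to_numpy(dtype=np.float64)
    r2 = float(sm.OLS(y, X).fit().rsquared)
    rng = np.random.default_rng(seed)
    n = len(y)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, yb = X[idx], y[idx]
        if np.linalg.matrix_rank(Xb) < X.shape[1] or np.std(yb) == 0:
            boots[b] = r2
            continue
        boots[b] = sm.OLS(yb, Xb).fit().rsquared
    lo, hi = np.quantile(boots, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return r2, (float(lo), float(hi))
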