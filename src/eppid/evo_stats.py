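"""Statistics relating network metrics to protein evolutionary rate.

The battery mirrors the classical evolutionary-rate covariate analyses:
Spearman rank correlation and first-order partial Spearman correlation
(controlling for abundance), percent variance explained by simple linear
regression with and without a residual-regression abundance control, a
principal component regression of dN on six standardized predictors, and
group tests (one-sided Wilcoxon rank-sum, Fisher's exact) for class
comparisons.

Correlation p-values are two-sided throughout this module; the one-sided
positive-correlation test lives in :mod:`eppid.coexpression` where the
declared direction is part of the hypothesis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    controlled_for: str | None = None


@dataclass
class PCRResult:
    """Principal component regression output.

    ``component_variance_pct[k]`` is the percent of response variance
    explained by component k alone (components are orthogonal, so these sum
    to the full-model R-squared x 100).  ``contribution_pct`` is a
    variables x components table of squared eigenvector loadings x 100;
    each column sums to 100.
    """

    component_variance_pct: np.ndarray
    contribution_pct: pd.DataFrame
    component_pvalues: np.ndarray
    total_variance_pct: float
    n: int

    def significance_codes(self) -> list[str]:
        """Map component p-values to the conventional star codes."""
        codes = []
        for p in self.component_pvalues:
            if p < 0.001:
                codes.append("***")
            elif p < 0.05:
                codes.append("*")
            elif p < 0.10:
                codes.append("#")
            else:
                codes.append("")
        return codes


def _clean_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p-value from the t-approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n - 2 degrees of freedom.
    Constant input yields an NA result.
    """
    x, y = _clean_xy(x, y)
    n = len(x)
    if n < 4:
        raise ValidationError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rho=float("nan"), p=float("nan"), n=n)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n=n)


def partial_spearman(x, y, ctrl, ctrl_name: str = "ctrl") -> CorrelationResult:
    """First-order partial Spearman correlation of x and y given a control.

    ``rho_xy.c = (rho_xy - rho_xc * rho_yc) / sqrt((1-rho_xc^2)(1-rho_yc^2))``
    with a two-sided p-value from a t-statistic on n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(ctrl, dtype=float)
    if not (x.shape == y.shape == c.shape) or x.ndim != 1:
        raise ValidationError("x, y and ctrl must be equal-length vectors")
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    x, y, c = x[keep], y[keep], c[keep]
    n = len(x)
    if n < 5:
        raise ValidationError("need at least 5 paired observations")
    r_xy = stats.spearmanr(x, y).statistic
    r_xc = stats.spearmanr(x, c).statistic
    r_yc = stats.spearmanr(y, c).statistic
    denom = (1 - r_xc**2) * (1 - r_yc**2)
    if denom <= 1e-12:
        raise ValidationError("control is rank-collinear with x or y")
    rho = (r_xy - r_xc * r_yc) / np.sqrt(denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(rho=rho, p=p, n=n, controlled_for=ctrl_name)


def _transform(v: np.ndarray, log: bool, const: float) -> np.ndarray:
    v = v + const
    if log:
        if np.any(v <= 0):
            raise ValidationError("log transform requires positive values (after constant)")
        v = np.log(v)
    return v


def variance_explained(
    x,
    y,
    log_x: bool = False,
    log_y: bool = False,
    const_x: float = 0.0,
    const_y: float = 0.0,
) -> tuple[float, float]:
    """Percent variance of y explained by a simple linear regression on x.

    Optional natural-log transforms with additive constants applied first
    (e.g. dN + 0.001, ePPID or betweenness + 0.1 to avoid zeros).
    Returns ``(R^2 x 100, two-sided slope p-value)``; NA on a
    zero-variance predictor.
    """
    x, y = _clean_xy(x, y)
    x = _transform(x, log_x, const_x)
    y = _transform(y, log_y, const_y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2 * 100), float(fit.pvalue)


def variance_explained_controlled(
    x,
    y,
    ctrl,
    log_y: bool = False,
    const_y: float = 0.0,
) -> tuple[float, float]:
    """Percent variance of y explained by x after regressing out a control.

    Fits ``y ~ ctrl`` by least squares, takes the residual, then regresses
    the residual on x; returns that regression's R^2 x 100 and slope p.
    The control (e.g. log abundance) is expected to be transformed upstream.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(ctrl, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    x, y, c = x[keep], y[keep], c[keep]
    if len(x) < 4:
        raise ValidationError("need at least 4 complete observations")
    y = _transform(y, log_y, const_y)
    if np.ptp(c) == 0 or np.ptp(x) == 0:
        return float("nan"), float("nan")
    fit_c = stats.linregress(c, y)
    residual = y - (fit_c.intercept + fit_c.slope * c)
    # a response fully determined by the control leaves only float noise
    if np.var(residual) <= 1e-12 * max(np.var(y), 1e-300):
        return 0.0, float("nan")
    fit = stats.linregress(x, residual)
    return float(fit.rvalue**2 * 100), float(fit.pvalue)


def pcr(
    predictors: pd.DataFrame,
    response: pd.Series,
    no_log: tuple = ("dispensability",),
    constants: dict | None = None,
    response_constant: float = 0.001,
    response_log: bool = True,
) -> PCRResult:
    """Principal component regression of evolutionary rate on predictors.

    All predictors are natural-log transformed (except those named in
    ``no_log``) after adding any per-variable constant from ``constants``
    (e.g. 0.1 for ePPID and betweenness), then standardized to zero mean
    and unit variance.  The response defaults to ``ln(dN + 0.001)``.  The
    predictor correlation matrix is eigen-decomposed; component scores are
    the standardized predictors projected on the eigenvectors.  Per
    component: percent response variance explained (squared correlation of
    the response with the score x 100) and a two-sided slope p-value.
    Percent contribution of variable j to component k is the squared
    eigenvector entry x 100, so each component's contributions sum to 100.

    Complete cases only; rows with any missing value are dropped.
    """
    constants = dict(constants or {})
    data = predictors.copy()
    data["__response__"] = response
    data = data.dropna()
    n = len(data)
    n_vars = predictors.shape[1]
    if n < n_vars + 2:
        raise ValidationError(f"only {n} complete cases for {n_vars} predictors")
    if n < 10 * n_vars:
        logger.warning("PCR with %d rows for %d predictors; results may be unstable", n, n_vars)

    y = _transform(data["__response__"].to_numpy(), response_log, response_constant)
    X = np.column_stack(
        [
            _transform(
                data[col].to_numpy(dtype=float),
                log=col not in no_log,
                const=constants.get(col, 0.0),
            )
            for col in predictors.columns
        ]
    )
    stds = X.std(axis=0, ddof=1)
    if np.any(stds == 0):
        bad = [c for c, s in zip(predictors.columns, stds) if s == 0]
        raise ValidationError(f"zero-variance predictors: {bad}")
    Z = (X - X.mean(axis=0)) / stds

    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[-1] < 1e-10:
        loading = np.abs(eigvecs[:, -1])
        involved = [
            str(c) for c, w in zip(predictors.columns, loading) if w > 0.3
        ]
        raise ValidationError(f"singular predictor correlation matrix; collinear: {involved}")

    scores = Z @ eigvecs
    comp_var = np.empty(n_vars)
    comp_p = np.empty(n_vars)
    for k in range(n_vars):
        fit = stats.linregress(scores[:, k], y)
        comp_var[k] = fit.rvalue**2 * 100
        comp_p[k] = fit.pvalue
    contribution = pd.DataFrame(
        eigvecs**2 * 100,
        index=predictors.columns,
        columns=[f"PC{k + 1}" for k in range(n_vars)],
    )
    return PCRResult(
        component_variance_pct=comp_var,
        contribution_pct=contribution,
        component_pvalues=comp_p,
        total_variance_pct=float(comp_var.sum()),
        n=n,
    )


def wilcoxon_one_sided(lower, higher) -> float:
    """One-sided Wilcoxon rank-sum p for the alternative 'first group lower'.

    Exact null distribution for small tie-free samples, normal
    approximation with tie correction otherwise (scipy's ``auto`` policy).
    """
    lower = np.asarray(lower, dtype=float)
    higher = np.asarray(higher, dtype=float)
    lower = lower[np.isfinite(lower)]
    higher = higher[np.isfinite(higher)]
    if len(lower) == 0 or len(higher) == 0:
        raise ValidationError("both groups must be non-empty")
    if min(len(lower), len(higher)) < 3:
        logger.warning("group with fewer than 3 observations; p-value is unstable")
    return float(stats.mannwhitneyu(lower, higher, alternative="less").pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 contingency table."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValidationError("Fisher's exact test needs a 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def group_tests(groups: dict) -> pd.DataFrame:
    """Pairwise one-sided Wilcoxon tests between labeled dN groups.

    For each ordered pair (A, B) reports the p-value for the alternative
    that group A's values are stochastically lower than group B's.
    """
    labels = [k for k, v in groups.items() if len(v) > 0]
    if len(labels) < 2:
        raise ValidationError("need at least two non-empty groups")
    rows = []
    for a in labels:
        for b in labels:
            if a == b:
                continue
            rows.append(
                {
                    "lower_group": a,
                    "higher_group": b,
                    "n_lower": len(groups[a]),
                    "n_higher": len(groups[b]),
                    "p": wilcoxon_one_sided(groups[a], groups[b]),
                }
            )
    return pd.DataFrame(rows)
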