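"""Tuning-parameter selection, post-fit gene-wise tests, and AUC scoring.

The tuning parameter lambda is derived from a significance level q via the
null distribution of the keep/kill statistic: chi-squared with p degrees of
freedom for the type-I penalty (lambda = F^-1(1-q; p) / 2) and a standard
Gaussian for the type-II penalty (lambda = [Phi^-1(1-q/2)]^2 / 2); the two
coincide at p = 1.

For ranking genes, the estimated normalization offsets are subtracted from
the data, which decouples the joint model into m ordinary gene-wise
regressions; the default test is the overall F-test of those regressions
(t-test on the target coordinate for type II). A known-variance chi-squared
variant based on the selection statistic itself is also provided — with it,
thresholding p-values at q reproduces the l0 selection exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .centering import _values
from .exceptions import ValidationError
from .fit import FitResult

__all__ = ["select_lambda", "gene_pvalues", "compute_auc"]


def select_lambda(q: float, p: int = 1, penalty_type: str = "type1") -> float:
    """Tuning parameter implied by significance level q (shared by all genes)."""
    if not 0.0 < q < 1.0:
        raise ValidationError("q must lie strictly between 0 and 1")
    if p < 1:
        raise ValidationError("p must be >= 1")
    if penalty_type == "type1":
        return 0.5 * float(stats.chi2.ppf(1.0 - q, df=p))
    if penalty_type == "type2":
        return 0.5 * float(stats.norm.ppf(1.0 - q / 2.0)) ** 2
    raise ValidationError("penalty_type must be 'type1' or 'type2'")


def _ols_f_pvalues(z: np.ndarray, x: np.ndarray, penalty_type: str) -> np.ndarray:
    """Gene-wise regression tests of the normalized data on the covariates.

    z is y - dhat (m x n); the design includes an intercept. Type I: overall
    F-test for all slopes zero. Type II: two-sided t-test on the last slope.
    Constant genes get p-value 1.
    """
    m, n = z.shape
    p = x.shape[1]
    df_resid = n - p - 1
    if df_resid < 1:
        raise ValidationError("need n - p - 1 >= 1 for the gene-wise F/t tests")

    design = np.column_stack([np.ones(n), x])
    gram_inv = np.linalg.inv(design.T @ design)
    coef = z @ design @ gram_inv.T                       # (m, p+1)
    resid = z - coef @ design.T
    sse = (resid * resid).sum(axis=1)
    zc = z - z.mean(axis=1, keepdims=True)
    sst = (zc * zc).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = sse / df_resid
        if penalty_type == "type1":
            fstat = ((sst - sse) / p) / s2
            pvals = stats.f.sf(fstat, p, df_resid)
        else:
            se = np.sqrt(s2 * gram_inv[p, p])
            tstat = coef[:, p] / se
            pvals = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    # Degenerate genes: zero total variation after normalization -> no signal.
    pvals = np.asarray(pvals)
    pvals[~np.isfinite(pvals)] = 1.0
    pvals[sst <= 0] = 1.0
    return np.clip(pvals, 0.0, 1.0)


def gene_pvalues(Y, X, fit: FitResult, method: str = "ols_f") -> np.ndarray:
    """Per-gene p-values for the no-association null, after normalization.

    ``ols_f`` (default): substitute the estimated offsets dhat into the
    model and run decoupled per-gene regressions with estimated residual
    variance. ``chisq_known_var``: tail probability of the fit's own
    selection statistic (chi-squared with p df for type I, two-sided
    Gaussian for type II) under the variances the fit was given.
    """
    y = _values(Y)
    x = _values(X)
    if x.ndim == 1:
        x = x[:, None]
    ptype = fit.penalty.penalty_type
    if method == "ols_f":
        z = y - fit.d[None, :]
        return _ols_f_pvalues(z, x, ptype)
    if method == "chisq_known_var":
        # fit.stat = statistic / 2 on the chi-squared scale.
        if ptype == "type1":
            return np.asarray(stats.chi2.sf(2.0 * fit.stat, df=x.shape[1]))
        return np.asarray(2.0 * stats.norm.sf(np.sqrt(2.0 * fit.stat)))
    raise ValidationError("method must be 'ols_f' or 'chisq_known_var'")


def compute_auc(pvalues: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve of the ranking by ascending p-value.

    Mann-Whitney formulation; ties count 1/2. Requires both classes.
    """
    from sklearn.metrics import roc_auc_score

    pvalues = np.asarray(pvalues, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if pvalues.shape != labels.shape:
        raise ValidationError("pvalues and labels must have the same shape")
    if labels.all() or not labels.any():
        raise ValidationError("AUC is undefined with a single class")
    return float(roc_auc_score(labels, -pvalues))
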