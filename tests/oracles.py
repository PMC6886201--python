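"""Independent brute-force oracles shared by the fit and acceptance tests.

These deliberately re-derive every quantity from first principles (support
enumeration, literal objective evaluation) and never call into the solver
paths they are checking.
"""

import itertools

import numpy as np

from jointde._linalg import ols_coefficients, project_out


def enumerate_type1_optimum(cd, var, lam):
    """Minimize the profiled whole-vector-penalty objective over every
    keep/kill support pattern; per pattern the optimal shared parameter is
    the killed genes' precision-weighted mean candidate (closed form),
    because kept genes' residuals do not depend on it."""
    b = ols_coefficients(cd.x_tilde, cd.y_tilde)
    gram = cd.x_tilde.T @ cd.x_tilde
    resid = cd.y_tilde - b @ cd.x_tilde.T
    rss_half = (resid * resid).sum(axis=1) / (2.0 * var)
    w = 1.0 / var
    best = np.inf
    for keep in itertools.product([False, True], repeat=cd.m):
        keep = np.array(keep)
        kill = ~keep
        obj = rss_half.sum() + lam[keep].sum()
        if kill.any():
            delta = -(w[kill][:, None] * b[kill]).sum(axis=0) / w[kill].sum()
            dev = b[kill] + delta[None, :]
            obj += ((dev @ gram) * dev).sum(axis=1) @ (w[kill] / 2.0)
        best = min(best, obj)
    return best


def enumerate_type2_optimum(cd, var, lam):
    """Support enumeration for the single-coordinate penalty: killed genes
    pay the residualized-target quadratic, kept genes pay lambda."""
    xp = cd.x_tilde[:, -1]
    xp_res = project_out(cd.x_tilde[:, :-1], xp[None, :])[0]
    s = xp_res @ xp_res
    b0 = (cd.y_tilde @ xp_res) / s
    a = s / (2.0 * var)
    bfull = ols_coefficients(cd.x_tilde, cd.y_tilde)
    resid = cd.y_tilde - bfull @ cd.x_tilde.T
    rss_half = (resid * resid).sum(axis=1) / (2.0 * var)
    best = np.inf
    for keep in itertools.product([False, True], repeat=cd.m):
        keep = np.array(keep)
        kill = ~keep
        obj = rss_half.sum() + lam[keep].sum()
        if kill.any():
            delta_p = -(a[kill] * b0[kill]).sum() / a[kill].sum()
            obj += (a[kill] * (b0[kill] + delta_p) ** 2).sum()
        best = min(best, obj)
    return best


def direct_objective_type1(cd, var, lam, beta, delta):
    """Literal term-by-term evaluation of the penalized profiled objective."""
    total = 0.0
    for i in range(cd.m):
        r = cd.y_tilde[i] + cd.x_tilde @ delta - cd.x_tilde @ beta[i]
        total += (r @ r) / (2.0 * var[i])
        if np.any(beta[i] != 0):
            total += lam[i]
    return total
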