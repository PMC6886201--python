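"""The l0-penalized joint fit (normalization + differential expression).

After profiling out gene intercepts and sample offsets, the penalized
objective over per-gene coefficient vectors beta_i is

    f(beta) = sum_i (1/2 sigma_i^2) || ytilde_i + Xtilde delta - Xtilde beta_i ||^2
              + sum_i lambda_i * penalty(beta_i),

where delta is the inverse-variance weighted mean of the beta_i (the shared
parameter coupling genes through the normalization) and the penalty counts
whether beta_i is nonzero (type I: the whole vector; type II: only its last
coordinate, all other covariates being adjustment variables).

For fixed delta the problem separates over genes and each gene has a
closed-form solution: keep the unpenalized OLS coefficient when the scaled
explained sum of squares reaches lambda_i, otherwise kill it to zero
(strict "<" kills; a tie keeps). What remains is a 1-D (or p-D) search over
delta of a sum of capped quadratics, performed by a dense grid plus local
refinement; the objective is piecewise quadratic so the global optimum lies
near one of finitely many breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .centering import (
    CenteredData,
    CovariateMatrix,
    LogExpressionMatrix,
    center_data,
    weighted_beta_mean,
    _values,
)
from .exceptions import UnidentifiableError, ValidationError
from .variance import NoiseVariances
from ._linalg import ols_coefficients, project_out

__all__ = [
    "PenaltySpec",
    "FitResult",
    "ols_betas",
    "type1_keep_rule",
    "type1_delta_objective",
    "optimize_delta_type1",
    "fit_type1",
    "beta_p_ols",
    "type2_keep_rule",
    "fit_type2",
    "recover_normalization",
]

#: Number of points in the 1-D delta grid.
GRID_POINTS = 2001
#: Per-axis points of the 2-D tensor grid.
GRID_POINTS_2D = 201
#: Relative padding added to the candidate range before gridding.
GRID_PAD = 0.10


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty type plus per-gene tuning parameters (scalar broadcasts)."""

    penalty_type: str = "type1"
    lambdas: float | np.ndarray = 0.0
    q: float | None = None

    def __post_init__(self) -> None:
        if self.penalty_type not in ("type1", "type2"):
            raise ValidationError("penalty_type must be 'type1' or 'type2'")
        if np.any(np.asarray(self.lambdas) < 0):
            raise ValidationError("lambdas must be non-negative")

    def lambda_vector(self, m: int) -> np.ndarray:
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim == 0:
            return np.full(m, float(lam))
        if lam.shape != (m,):
            raise ValidationError("lambdas must be scalar or one value per gene")
        return lam


@dataclass
class FitResult:
    """Joint-fit output.

    `delta_opt` is the shared-parameter value found by the global search
    (the `objective` is the penalized profile objective evaluated there),
    while `delta` is recomputed from the final thresholded coefficients via
    the weighted mean so that the recovered d and alpha satisfy the
    stationarity identities exactly. `stat` holds each gene's keep/kill
    statistic, comparable to its lambda.
    """

    beta: np.ndarray          # (m, p), zero rows (or zero last coordinate) killed
    delta: np.ndarray         # (p,) weighted mean of final beta
    delta_opt: np.ndarray     # (p,) optimizer of the profile objective
    alpha: np.ndarray         # (m,)
    d: np.ndarray             # (n,), d[0] == 0
    selected: np.ndarray      # (m,) bool
    objective: float
    beta_ols: np.ndarray      # (m, p) unpenalized solutions at delta_opt
    stat: np.ndarray          # (m,) keep/kill statistic
    penalty: PenaltySpec
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# type I penalty
# ---------------------------------------------------------------------------

def ols_betas(cd: CenteredData, delta) -> np.ndarray:
    """Per-gene unpenalized coefficients (XtX)^-1 Xt ytilde_i + delta."""
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    b = ols_coefficients(cd.x_tilde, cd.y_tilde)
    return b + delta[None, :]


def _type1_stat(cd: CenteredData, variances, betas) -> np.ndarray:
    """Keep/kill statistic (1 / 2 sigma_i^2) ||Xtilde beta_i||^2."""
    var = np.asarray(variances, dtype=float)
    fitted = cd.x_tilde @ np.asarray(betas, dtype=float).T  # (n, m)
    return (fitted * fitted).sum(axis=0) / (2.0 * var)


def type1_keep_rule(cd: CenteredData, variances, lambdas, delta):
    """Threshold the OLS solutions: kill gene i when its statistic < lambda_i.

    Returns (selected boolean mask, thresholded (m, p) beta matrix).
    """
    lam = np.asarray(lambdas, dtype=float)
    bols = ols_betas(cd, delta)
    stat = _type1_stat(cd, variances, bols)
    selected = stat >= lam
    beta = np.where(selected[:, None], bols, 0.0)
    return selected, beta


def type1_delta_objective(cd: CenteredData, variances, lambdas, delta) -> float:
    """Profile objective in delta: sum_i min(statistic_i(delta), lambda_i)."""
    lam = np.asarray(lambdas, dtype=float)
    bols = ols_betas(cd, delta)
    stat = _type1_stat(cd, variances, bols)
    return float(np.minimum(stat, lam).sum())


def _grid_1d(candidates: np.ndarray, points: int) -> np.ndarray:
    lo, hi = float(candidates.min()), float(candidates.max())
    width = hi - lo
    if width == 0.0:
        return np.array([lo])
    pad = GRID_PAD * width
    return np.linspace(lo - pad, hi + pad, points)


def _capped_quadratic_sum(a: np.ndarray, b: np.ndarray, lam: np.ndarray,
                          grid: np.ndarray) -> np.ndarray:
    """sum_i min(a_i (b_i + delta)^2, lam_i) over a vector of deltas.

    Evaluated in chunks to bound memory at large m.
    """
    out = np.empty(grid.shape[0])
    chunk = max(1, int(4_000_000 // max(a.shape[0], 1)))
    for start in range(0, grid.shape[0], chunk):
        g = grid[start:start + chunk]
        vals = a[:, None] * (b[:, None] + g[None, :]) ** 2
        np.minimum(vals, lam[:, None], out=vals)
        out[start:start + chunk] = vals.sum(axis=0)
    return out


def _minimize_capped_1d(a: np.ndarray, b: np.ndarray, lam: np.ndarray) -> float:
    """Global 1-D search: dense grid over the candidate minimizers {-b_i}
    padded by 10%, followed by bounded golden-section refinement inside the
    best grid cell. Flat objectives return 0 (documented tie-break)."""
    grid = _grid_1d(-b, GRID_POINTS)
    vals = _capped_quadratic_sum(a, b, lam, grid)
    if np.ptp(vals) == 0.0:
        return 0.0
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.shape[0] - 1)]
    if hi <= lo:
        return float(grid[k])

    def f(delta: float) -> float:
        return float(np.minimum(a * (b + delta) ** 2, lam).sum())

    res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    best = float(res.x) if res.fun <= vals[k] else float(grid[k])
    return best


def optimize_delta_type1(cd: CenteredData, variances, lambdas,
                         seed: int = 0) -> np.ndarray:
    """Globally optimize the shared parameter delta of the type-I profile.

    p = 1: dense grid + golden-section refinement (exact up to grid
    resolution, the objective being piecewise quadratic). p = 2: tensor
    grid with local polish. p > 2: seeded multi-start local optimization
    from per-gene candidate minimizers; best objective wins, ties broken by
    the smallest ||delta||.
    """
    if cd.m == 0:
        raise ValidationError("cannot optimize delta with no genes")
    var = np.asarray(variances, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    if lam.ndim == 0:
        lam = np.full(cd.m, float(lam))
    b = ols_coefficients(cd.x_tilde, cd.y_tilde)  # (m, p), delta-free part
    p = cd.p

    if p == 1:
        a = (cd.x_tilde[:, 0] ** 2).sum() / (2.0 * var)
        return np.array([_minimize_capped_1d(a, b[:, 0], lam)])

    xtx = cd.x_tilde.T @ cd.x_tilde

    def objective(delta: np.ndarray) -> float:
        fitted = cd.x_tilde @ (b + delta[None, :]).T
        stat = (fitted * fitted).sum(axis=0) / (2.0 * var)
        return float(np.minimum(stat, lam).sum())

    if p == 2:
        g0 = _grid_1d(-b[:, 0], GRID_POINTS_2D)
        g1 = _grid_1d(-b[:, 1], GRID_POINTS_2D)
        best_val, best = np.inf, np.zeros(2)
        for d0 in g0:
            # vectorize the inner axis
            deltas = np.column_stack([np.full(g1.shape[0], d0), g1])
            fitted = cd.x_tilde @ (b[None, :, :] + deltas[:, None, :]).transpose(0, 2, 1)
            stat = (fitted * fitted).sum(axis=1) / (2.0 * var)[None, :]
            vals = np.minimum(stat, lam[None, :]).sum(axis=1)
            k = int(np.argmin(vals))
            if vals[k] < best_val:
                best_val, best = float(vals[k]), deltas[k]
        starts = [best]
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(cd.m, size=min(10, cd.m), replace=False)
        starts = [-b[i] for i in idx] + [np.zeros(p)]

    best_val, best = np.inf, np.zeros(p)
    for s in starts:
        res = optimize.minimize(objective, s, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 2000})
        val = float(res.fun)
        cand = np.asarray(res.x)
        if val < best_val - 1e-12 or (
            abs(val - best_val) <= 1e-12
            and np.linalg.norm(cand) < np.linalg.norm(best)
        ):
            best_val, best = val, cand
    if objective(np.zeros(p)) <= best_val and np.ptp(lam) == 0 and lam[0] == 0:
        return np.zeros(p)
    return best


def recover_normalization(cd: CenteredData, beta, variances=None):
    """Recover sample offsets d (d_1 = 0) and gene intercepts alpha from a
    (thresholded) coefficient matrix, using the weighted mean of beta."""
    beta = np.asarray(beta, dtype=float)
    var = cd.variances_used if variances is None else np.asarray(variances, float)
    beta_bar = weighted_beta_mean(beta, var)
    dx = cd.x_tilde - cd.x_tilde[0]
    d = (cd.weighted_col_means - cd.weighted_col_means[0]) - dx @ beta_bar
    alpha = (
        cd.row_means
        + cd.weighted_col_means[0]
        - cd.grand_weighted_mean
        - cd.x_tilde[0] @ beta_bar
        - beta @ cd.covariate_means
    )
    d[0] = 0.0  # exact by construction; enforce against roundoff
    return d, alpha


def _as_matrices(Y, X):
    y = _values(Y)
    x = _values(X)
    if x.ndim == 1:
        x = x[:, None]
    gene_ids = list(getattr(Y, "gene_ids", []) or [])
    sample_ids = list(getattr(Y, "sample_ids", []) or [])
    return y, x, gene_ids, sample_ids


def _resolve_variances(variances, m: int) -> np.ndarray:
    if isinstance(variances, NoiseVariances):
        var = variances.shrunk
    else:
        var = np.asarray(variances, dtype=float)
        if var.ndim == 0:
            var = np.full(m, float(var))
    if var.shape != (m,):
        raise ValidationError("variances must provide one value per gene")
    return var


def fit_type1(Y, X, variances, lambdas, seed: int = 0) -> FitResult:
    """Complete type-I joint fit (any-covariate association).

    Centers the data, globally optimizes the shared parameter, applies the
    keep/kill rule, then recovers normalization offsets and intercepts from
    the final coefficients.
    """
    y, x, gene_ids, sample_ids = _as_matrices(Y, X)
    var = _resolve_variances(variances, y.shape[0])
    lam = PenaltySpec("type1", lambdas).lambda_vector(y.shape[0])

    cd = center_data(y, x, var)
    delta_opt = optimize_delta_type1(cd, var, lam, seed=seed)
    bols = ols_betas(cd, delta_opt)
    stat = _type1_stat(cd, var, bols)
    selected = stat >= lam
    beta = np.where(selected[:, None], bols, 0.0)

    # Penalized profile objective at the optimizer: residual base + capped part.
    resid = cd.y_tilde - (bols - delta_opt[None, :]) @ cd.x_tilde.T
    base = float(((resid * resid).sum(axis=1) / (2.0 * var)).sum())
    objective = base + float(np.minimum(stat, lam).sum())

    delta_final = weighted_beta_mean(beta, var)
    d, alpha = recover_normalization(cd, beta)
    return FitResult(
        beta=beta, delta=delta_final, delta_opt=delta_opt, alpha=alpha, d=d,
        selected=selected, objective=objective, beta_ols=bols, stat=stat,
        penalty=PenaltySpec("type1", lam), gene_ids=gene_ids,
        sample_ids=sample_ids,
    )


# ---------------------------------------------------------------------------
# type II penalty
# ---------------------------------------------------------------------------

def _residualized_target(cd: CenteredData):
    """Project the adjustment covariates out of the target (last) covariate.

    Returns (xp_res, s) where xp_res is the residualized column and
    s = ||xp_res||^2.
    """
    xp = cd.x_tilde[:, -1]
    xminus = cd.x_tilde[:, :-1]
    xp_res = project_out(xminus, xp[None, :])[0]
    s = float(xp_res @ xp_res)
    if s <= 1e-12 * max(float(xp @ xp), 1.0):
        raise UnidentifiableError(
            "target covariate is collinear with the adjustment covariates"
        )
    return xp_res, s


def beta_p_ols(cd: CenteredData, delta_p: float) -> np.ndarray:
    """Last coordinate of the per-gene OLS solution, via the partitioned
    (residualize-then-regress) form; reduces to plain OLS when p = 1."""
    xp_res, s = _residualized_target(cd)
    return (cd.y_tilde @ xp_res) / s + float(delta_p)


def type2_keep_rule(cd: CenteredData, variances, lambdas, delta_p: float):
    """Threshold only the target coordinate.

    Kept genes carry the full OLS vector; killed genes get beta_ip = 0 with
    the remaining coordinates refit under the reduced model (which includes
    the x^p * delta_p correction). Strict "<" kills, ties keep.
    """
    var = np.asarray(variances, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    xp_res, s = _residualized_target(cd)
    bp = (cd.y_tilde @ xp_res) / s + float(delta_p)
    stat = s * bp * bp / (2.0 * var)
    selected = stat >= lam

    m, p = cd.m, cd.p
    beta = np.zeros((m, p))
    full = ols_betas(cd, np.r_[np.zeros(p - 1), float(delta_p)])
    beta[selected] = full[selected]
    if p > 1 and np.any(~selected):
        xminus = cd.x_tilde[:, :-1]
        resp = cd.y_tilde[~selected] + cd.x_tilde[:, -1][None, :] * float(delta_p)
        beta[~selected, :-1] = ols_coefficients(xminus, resp)
    return selected, beta


def fit_type2(Y, X, variances, lambdas, seed: int = 0) -> FitResult:
    """Complete type-II joint fit (one covariate of interest, adjusted).

    The shared parameter reduces to the scalar delta_p of the target
    coordinate; it is optimized by the same 1-D grid-plus-refinement search
    as the type-I p = 1 case. Coincides exactly with fit_type1 when p = 1.
    """
    y, x, gene_ids, sample_ids = _as_matrices(Y, X)
    var = _resolve_variances(variances, y.shape[0])
    lam = PenaltySpec("type2", lambdas).lambda_vector(y.shape[0])

    cd = center_data(y, x, var)
    xp_res, s = _residualized_target(cd)
    b0 = (cd.y_tilde @ xp_res) / s           # delta_p-free part of beta_ip
    a = s / (2.0 * var)
    delta_p = _minimize_capped_1d(a, b0, lam)

    selected, beta = type2_keep_rule(cd, var, lam, delta_p)
    bp = b0 + delta_p
    stat = a * bp * bp
    bols = ols_betas(cd, np.r_[np.zeros(cd.p - 1), delta_p])

    # Objective: full-model residual base + capped part (same algebra as type I
    # with the statistic residualized onto the target covariate).
    resid = cd.y_tilde - (bols - np.r_[np.zeros(cd.p - 1), delta_p][None, :]) @ cd.x_tilde.T
    base = float(((resid * resid).sum(axis=1) / (2.0 * var)).sum())
    objective = base + float(np.minimum(stat, lam).sum())

    delta_final = weighted_beta_mean(beta, var)
    d, alpha = recover_normalization(cd, beta)
    delta_opt = np.r_[np.zeros(cd.p - 1), delta_p]
    return FitResult(
        beta=beta, delta=delta_final, delta_opt=delta_opt, alpha=alpha, d=d,
        selected=selected, objective=objective, beta_ols=bols, stat=stat,
        penalty=PenaltySpec("type2", lam), gene_ids=gene_ids,
        sample_ids=sample_ids,
    )
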