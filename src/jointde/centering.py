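"""Data containers and the weighted double-centering transform.

The joint model for log expression is

    y_ij = alpha_i + beta_i' x_j + d_j + eps_ij,   eps_ij ~ N(0, sigma_i^2),

with gene intercepts alpha_i, per-gene coefficient vectors beta_i on p
continuous covariates x_j, and sample normalization offsets d_j (d_1 = 0 by
convention). Profiling alpha and d out of the penalized likelihood leaves a
regression on doubly centered data: responses

    ytilde_ij = y_ij - ybar_i. - ybar_.j^(w) + ybar^(w)

(plain row means, inverse-variance weighted column means and grand mean) and
centered covariates xtilde_j = x_j - xbar. This module houses those
containers and the centering itself; the l0 fit operates on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import UnidentifiableError, ValidationError
from ._linalg import qr_factor

__all__ = [
    "LogExpressionMatrix",
    "CovariateMatrix",
    "CenteredData",
    "center_data",
    "weighted_beta_mean",
]


def _default_ids(prefix: str, k: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(k)]


@dataclass
class LogExpressionMatrix:
    """m x n matrix of log-transformed expression values with identifiers."""

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if not self.gene_ids:
            self.gene_ids = _default_ids("gene_", m)
        if not self.sample_ids:
            self.sample_ids = _default_ids("sample_", n)
        if len(self.gene_ids) != m or len(self.sample_ids) != n:
            raise ValidationError("id lengths do not match matrix shape")
        if len(set(self.gene_ids)) != m:
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CovariateMatrix:
    """n x p matrix of continuous experimental conditions."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValidationError("covariates must be a 2-D matrix")
        n, p = self.values.shape
        if not self.sample_ids:
            self.sample_ids = _default_ids("sample_", n)
        if not self.covariate_names:
            self.covariate_names = _default_ids("x", p)
        if len(self.sample_ids) != n or len(self.covariate_names) != p:
            raise ValidationError("id lengths do not match covariate shape")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("covariate values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CenteredData:
    """Doubly centered responses plus the means that built them.

    Satisfies (to numerical tolerance)
    ``sum_i y_tilde[i, j] / variances_used[i] == 0`` for every sample j and
    ``sum_j y_tilde[i, j] == 0`` for every gene i; columns of ``x_tilde``
    sum to zero.
    """

    y_tilde: np.ndarray
    x_tilde: np.ndarray
    weighted_col_means: np.ndarray
    row_means: np.ndarray
    grand_weighted_mean: float
    covariate_means: np.ndarray
    variances_used: np.ndarray

    @property
    def m(self) -> int:
        return self.y_tilde.shape[0]

    @property
    def n(self) -> int:
        return self.y_tilde.shape[1]

    @property
    def p(self) -> int:
        return self.x_tilde.shape[1]


def _values(obj) -> np.ndarray:
    return np.asarray(getattr(obj, "values", obj), dtype=float)


def center_data(Y, X, variances) -> CenteredData:
    """Profile the gene intercepts and sample offsets out of the data.

    Parameters
    ----------
    Y : LogExpressionMatrix or (m, n) array
    X : CovariateMatrix or (n, p) array
    variances : (m,) strictly positive noise variances defining the
        1/sigma^2 weights of the column means.
    """
    y = _values(Y)
    x = _values(X)
    if x.ndim == 1:
        x = x[:, None]
    var = np.asarray(variances, dtype=float)
    if var.ndim == 0:
        var = np.full(y.shape[0], float(var))
    if y.ndim != 2 or x.ndim != 2 or y.shape[1] != x.shape[0]:
        raise ValidationError(
            f"inconsistent shapes: Y {y.shape}, X {x.shape}"
        )
    if var.shape != (y.shape[0],):
        raise ValidationError("variances must be one value per gene")
    if not np.all(np.isfinite(var)) or np.any(var <= 0):
        raise ValidationError("variances must be finite and strictly positive")

    w = 1.0 / var
    wsum = w.sum()
    weighted_col_means = (w @ y) / wsum
    row_means = y.mean(axis=1)
    grand = float(w @ row_means / wsum)
    y_tilde = y - row_means[:, None] - weighted_col_means[None, :] + grand

    covariate_means = x.mean(axis=0)
    x_tilde = x - covariate_means
    try:
        qr_factor(x_tilde)
    except UnidentifiableError as err:
        raise UnidentifiableError(
            "centered covariate matrix is rank deficient (a covariate is "
            "constant or collinear after centering)"
        ) from err

    return CenteredData(
        y_tilde=y_tilde,
        x_tilde=x_tilde,
        weighted_col_means=weighted_col_means,
        row_means=row_means,
        grand_weighted_mean=grand,
        covariate_means=covariate_means,
        variances_used=var,
    )


def weighted_beta_mean(betas: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Inverse-variance weighted mean of per-gene coefficient vectors.

    This is the shared parameter (often written delta) that couples all
    genes through the normalization offsets: the 1/sigma_i^2-weighted
    average of the beta_i.
    """
    b = np.asarray(betas, dtype=float)
    if b.ndim == 1:
        b = b[:, None]
    var = np.asarray(variances, dtype=float)
    if np.any(var <= 0):
        raise ValidationError("variances must be strictly positive")
    w = 1.0 / var
    return (w @ b) / w.sum()
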