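"""Gene-wise noise-variance estimation.

Maximum-likelihood estimation alternates between (a) per-gene coefficient
updates given the current inverse-variance weights, (b) the weighted mean
coefficient, and (c) the residual-variance update with divisor n. Because
the weights enter the column centering, the weighted means are recomputed
every cycle. The raw MLEs are then robustified by shrinking each one toward
their grand mean with a data-driven weight, which stabilizes small-sample
estimates without changing the overall level (the mean of the shrunk
estimates equals the mean of the raw ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .centering import center_data, weighted_beta_mean, _values
from .exceptions import ValidationError
from ._linalg import ols_coefficients

__all__ = [
    "NoiseVariances",
    "VARIANCE_FLOOR",
    "estimate_variances",
    "shrink_variances",
    "estimate_noise_variances",
]

#: Lower bound applied to every sigma_i^2 so that 1/sigma^2 weights stay
#: finite for genes that are (numerically) constant across samples.
VARIANCE_FLOOR = 1e-8


@dataclass
class NoiseVariances:
    """Raw and shrunk gene-wise noise variance estimates."""

    raw: np.ndarray
    shrunk: np.ndarray
    shrink_weight: float
    mean_raw: float

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.shrunk = np.asarray(self.shrunk, dtype=float)


def _unweighted_double_center(y: np.ndarray) -> np.ndarray:
    row = y.mean(axis=1, keepdims=True)
    col = y.mean(axis=0, keepdims=True)
    return y - row - col + y.mean()


def estimate_variances(
    Y,
    X,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Alternating MLE of the gene-wise noise variances sigma_i^2.

    Initialization: per-gene variance of the unweighted doubly centered
    data, with the weighted-mean coefficient starting at zero. Stops when
    the maximum relative change in sigma^2 drops below `tol`, warning (and
    returning the last iterate) if `max_iter` is reached first. Each
    estimate is floored at VARIANCE_FLOOR.

    Returns the raw sigma_i^2 vector; see :func:`shrink_variances` for the
    robustified version.
    """
    y = _values(Y)
    x = _values(X)
    if x.ndim == 1:
        x = x[:, None]
    m, n = y.shape
    p = x.shape[1]
    if n <= p + 1:
        raise ValidationError(
            f"need n > p + 1 samples to estimate residual variances (n={n}, p={p})"
        )

    yc = _unweighted_double_center(y)
    sigma2 = np.maximum(yc.var(axis=1), VARIANCE_FLOOR)
    beta_bar = np.zeros(p)

    for _ in range(max_iter):
        cd = center_data(y, x, sigma2)
        b = ols_coefficients(cd.x_tilde, cd.y_tilde)  # coefficient w/o shared term
        beta = b + beta_bar
        beta_bar = weighted_beta_mean(beta, sigma2)
        resid = cd.y_tilde - b @ cd.x_tilde.T
        new = np.maximum((resid * resid).mean(axis=1), VARIANCE_FLOOR)
        rel = np.max(np.abs(new - sigma2) / sigma2)
        sigma2 = new
        if rel < tol:
            break
    else:
        warnings.warn(
            f"variance estimation did not converge in {max_iter} iterations "
            f"(last max relative change {rel:.3g}); returning last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return sigma2


def shrink_variances(raw: np.ndarray, n: int, p: int) -> NoiseVariances:
    """Shrink raw variance MLEs toward their grand mean.

    The shrink weight is ``w = 2(m-1)/(n-p+1) * (1/m + mean^2 / ss)`` with
    ``ss = sum_i (raw_i - mean)^2``, clamped to [0, 1] so the result stays
    a convex combination ``(1-w)*raw + w*mean``. If all raw values are
    identical (ss == 0) the formula degenerates; the common value is
    returned unchanged with w recorded as 1.
    """
    raw = np.asarray(raw, dtype=float)
    m = raw.shape[0]
    if m < 2:
        raise ValidationError("need at least two genes to shrink variances")
    if n <= p - 1:
        raise ValidationError("need n > p - 1 for the shrink weight")
    if np.any(raw <= 0):
        raise ValidationError("raw variances must be strictly positive")

    mean = float(raw.mean())
    ss = float(((raw - mean) ** 2).sum())
    if ss == 0.0:
        return NoiseVariances(raw=raw.copy(), shrunk=raw.copy(),
                              shrink_weight=1.0, mean_raw=mean)
    w = 2.0 * (m - 1) / (n - p + 1) * (1.0 / m + mean * mean / ss)
    w = float(min(max(w, 0.0), 1.0))
    shrunk = (1.0 - w) * raw + w * mean
    return NoiseVariances(raw=raw, shrunk=shrunk, shrink_weight=w, mean_raw=mean)


def estimate_noise_variances(
    Y,
    X,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> NoiseVariances:
    """Convenience wrapper: alternating MLE followed by shrinkage."""
    y = _values(Y)
    x = _values(X)
    if x.ndim == 1:
        x = x[:, None]
    raw = estimate_variances(y, x, tol=tol, max_iter=max_iter)
    return shrink_variances(raw, n=y.shape[1], p=x.shape[1])
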