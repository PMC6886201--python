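"""Single linear-algebra seam for the package.

All per-gene ordinary-least-squares solves go through a thin QR wrapper so
that rank deficiency surfaces as a typed :class:`UnidentifiableError`
instead of silently amplified noise.
"""

from __future__ import annotations

import numpy as np

from .exceptions import UnidentifiableError

# Relative tolerance on the R diagonal used to declare rank deficiency.
_RANK_RTOL = 1e-10


def qr_factor(design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Thin QR of an n x k design matrix, with a rank check.

    Raises UnidentifiableError when the design has (numerically) fewer than
    k independent columns.
    """
    design = np.asarray(design, dtype=float)
    if design.ndim != 2:
        raise ValueError("design must be 2-D")
    n, k = design.shape
    if k == 0:
        return np.empty((n, 0)), np.empty((0, 0))
    if n < k:
        raise UnidentifiableError(
            f"design has {n} rows but {k} columns; system is underdetermined"
        )
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    if scale == 0.0 or np.any(diag < _RANK_RTOL * scale):
        raise UnidentifiableError("design matrix is rank deficient")
    return q, r


def ols_coefficients(design: np.ndarray, responses: np.ndarray) -> np.ndarray:
    """OLS coefficients for many response vectors sharing one design.

    Parameters
    ----------
    design : (n, k) array
    responses : (m, n) array, one response per row.

    Returns
    -------
    (m, k) array of coefficients, row i solving
    ``min_b || responses[i] - design @ b ||^2``.
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    q, r = qr_factor(design)
    if design.shape[1] == 0:
        return np.empty((responses.shape[0], 0))
    # b = R^{-1} Q^T y, vectorized over genes.
    return np.linalg.solve(r, q.T @ responses.T).T


def project_out(design: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Residual of `vectors` (rows) after projecting onto col-space of design.

    With an empty design this is the identity.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if design.size == 0 or design.shape[1] == 0:
        return vectors.copy()
    q, _ = qr_factor(design)
    return vectors - (vectors @ q) @ q.T
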