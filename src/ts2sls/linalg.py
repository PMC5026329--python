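"""Small linear-algebra helpers with explicit singularity handling.

All matrix inversions in the package go through :func:`solve_psd` so that a
rank-deficient cross-product raises :class:`~ts2sls.exceptions.SingularMatrixError`
instead of silently falling back to a pseudo-inverse.
"""
from __future__ import annotations

import numpy as np

from .exceptions import SingularMatrixError

#: reciprocal condition number below which a Gram matrix is declared singular
RCOND_THRESHOLD = 1e-12


def rcond(a: np.ndarray) -> float:
    """Reciprocal condition number of a symmetric matrix (2-norm)."""
    s = np.linalg.svd(a, compute_uv=False)
    if s[0] == 0.0:
        return 0.0
    return float(s[-1] / s[0])


def check_nonsingular(a: np.ndarray, what: str = "matrix") -> None:
    r = rcond(np.atleast_2d(a))
    if r < RCOND_THRESHOLD:
        raise SingularMatrixError(
            f"{what} is numerically singular (reciprocal condition number "
            f"{r:.3e} < {RCOND_THRESHOLD:.0e})"
        )


def solve_psd(a: np.ndarray, b: np.ndarray, what: str = "matrix") -> np.ndarray:
    """Solve ``a @ x = b`` for symmetric positive-definite ``a``.

    Raises :class:`SingularMatrixError` when ``a`` is numerically singular.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    check_nonsingular(a, what)
    return np.linalg.solve(a, b)


def inv_psd(a: np.ndarray, what: str = "matrix") -> np.ndarray:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    return solve_psd(a, np.eye(a.shape[0]), what)


def symmetrize(a: np.ndarray) -> np.ndarray:
    """Average away floating-point asymmetry of a nominally symmetric matrix."""
    return 0.5 * (a + a.T)
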