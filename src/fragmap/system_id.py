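"""Per-window linear dynamical system identification.

Within a sliding window the multichannel voltage x(t) is modelled as a
discrete-time linear system x(t+1) = A x(t).  The state-transition matrix A
is estimated by ridge regression over the window's transition pairs:

    A = Y X^T (X X^T + lambda I)^{-1}

with X = [x(0) ... x(n-2)] and Y = [x(1) ... x(n-1)].  Stability of the
estimate (spectral radius < 1) is a precondition for a well-defined fragility
value, so when no ridge penalty is given the regularization is chosen
adaptively: fit at lambda = 1e-4 first; if the estimated dynamics are
unstable, bisect in log10(lambda) over [1e-4, 10] for up to 20 iterations,
keeping the smallest lambda whose fit is stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "LinearModelFit",
    "fit_window_model",
    "select_lambda",
    "spectral_radius",
    "STABILITY_TOL",
]

#: Numerical slack on the strict spectral-radius < 1 stability criterion.
STABILITY_TOL = 1e-12

#: Adaptive-regularization defaults.
LAMBDA_MIN = 1e-4
LAMBDA_MAX = 10.0
MAX_ITER = 20


@dataclass(frozen=True)
class LinearModelFit:
    """Ridge estimate of one window's state-transition matrix.

    Attributes
    ----------
    A : ndarray, shape (M, M)
        Estimated state-transition matrix.
    lam : float
        Ridge penalty used for the fit.
    spectral_radius : float
        Maximum eigenvalue modulus of ``A``.
    stable : bool
        Whether ``spectral_radius < 1`` (to :data:`STABILITY_TOL`).
    n_samples : int
        Window length (number of timepoints) the fit used.
    lambda_iterations : int
        Number of bisection steps the adaptive search spent (0 when the
        initial lambda was already stable or lambda was user-supplied).
    """

    A: np.ndarray
    lam: float
    spectral_radius: float
    stable: bool
    n_samples: int
    lambda_iterations: int = 0


def spectral_radius(A: np.ndarray) -> float:
    """Maximum modulus over the eigenvalues of a square matrix."""
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def _is_stable(rho: float) -> bool:
    return rho < 1.0 + STABILITY_TOL


def fit_window_model(window_data: np.ndarray, lam: float = 0.0,
                     lambda_iterations: int = 0) -> LinearModelFit:
    """Ridge-regression estimate of A from one window of multichannel data.

    Parameters
    ----------
    window_data : ndarray, shape (M, n)
        Voltage window; columns are consecutive timepoints.
    lam : float
        Ridge penalty (>= 0), added as an absolute term ``lam * I`` to the
        normal matrix (not scaled by window length).
    """
    Z = np.asarray(window_data, dtype=np.float64)
    if Z.ndim != 2:
        raise ValueError("window_data must be an M x n matrix")
    if not np.isfinite(Z).all():
        raise ValueError("window_data contains NaN or Inf")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    m, n = Z.shape
    if n < 2:
        raise ValueError("need at least 2 timepoints to form a transition pair")
    if n < m + 1:
        logger.warning(
            "window has n=%d samples for M=%d electrodes; the fit is underdetermined "
            "(n >= M+1 recommended)", n, m,
        )
    const_rows = np.nonzero(Z.std(axis=1) == 0)[0]
    if const_rows.size:
        raise ValueError(
            f"degenerate (all-constant) channel(s) at row index {const_rows.tolist()}; "
            "remove or check these electrodes"
        )
    X = Z[:, :-1]
    Y = Z[:, 1:]
    G = X @ X.T + lam * np.eye(m)
    try:
        # A^T solves (X X^T + lam I) A^T = X Y^T.
        At = scipy.linalg.solve(G, X @ Y.T, assume_a="pos")
    except scipy.linalg.LinAlgError as exc:
        if lam == 0:
            raise np.linalg.LinAlgError(
                "normal matrix X X^T is singular at lambda=0; pass a positive "
                "ridge penalty (e.g. 1e-4)"
            ) from exc
        raise
    A = At.T
    rho = spectral_radius(A)
    return LinearModelFit(
        A=A, lam=float(lam), spectral_radius=rho, stable=_is_stable(rho),
        n_samples=n, lambda_iterations=lambda_iterations,
    )


def select_lambda(window_data: np.ndarray, lambda_min: float = LAMBDA_MIN,
                  lambda_max: float = LAMBDA_MAX,
                  max_iter: int = MAX_ITER) -> LinearModelFit:
    """Adaptive ridge-penalty selection for a stable window fit.

    Fits at ``lambda_min`` first; a stable fit short-circuits the search.
    Otherwise the penalty is bisected in log10 space between the bounds for at
    most ``max_iter`` steps, keeping the smallest penalty whose fit is stable.
    If no penalty in the range stabilizes the estimate the ``lambda_max`` fit
    is returned flagged ``stable=False`` (fragility of an unstable estimate is
    ill-defined; downstream code carries the flag).
    """
    if not (0 < lambda_min < lambda_max):
        raise ValueError(f"need 0 < lambda_min < lambda_max, got ({lambda_min}, {lambda_max})")
    fit_lo = fit_window_model(window_data, lambda_min)
    if fit_lo.stable:
        return fit_lo
    fit_hi = fit_window_model(window_data, lambda_max)
    if not fit_hi.stable:
        logger.warning(
            "no stable fit in lambda range [%g, %g]; returning the lambda_max fit "
            "(spectral radius %.6f) flagged unstable", lambda_min, lambda_max,
            fit_hi.spectral_radius,
        )
        return fit_hi
    lo, hi = np.log10(lambda_min), np.log10(lambda_max)
    best = fit_hi
    iters = 0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        iters += 1
        fit_mid = fit_window_model(window_data, 10.0 ** mid, lambda_iterations=iters)
        if fit_mid.stable:
            best = fit_mid
            hi = mid
        else:
            lo = mid
    if best is fit_hi:
        best = LinearModelFit(
            A=fit_hi.A, lam=fit_hi.lam, spectral_radius=fit_hi.spectral_radius,
            stable=fit_hi.stable, n_samples=fit_hi.n_samples, lambda_iterations=iters,
        )
    return best
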