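"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed-form resolvent construction:
the minimum-norm destabilizing perturbation is found by constrained
optimization on the determinant condition det(A + Delta - lambda* I) = 0,
and ridge fits are checked against the explicit normal-equation inverse.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def oracle_min_norm(A: np.ndarray, lam_star: complex, k: int,
                    structure: str = "column", n_starts: int = 4,
                    seed: int = 0) -> float:
    """Minimum ||gamma||_2 such that lambda* is an eigenvalue of A + Delta.

    Delta is gamma e_k^T (column) or e_k gamma^T (row).  Solved by SLSQP on
    the real and imaginary parts of det(A + Delta - lambda* I) = 0 from
    several random starts; the constraint set is an affine subspace, so the
    problem is convex and any feasible local minimum is global.
    """
    A = np.asarray(A, dtype=float)
    m = A.shape[0]
    e_k = np.zeros(m)
    e_k[k] = 1.0
    eye = np.eye(m)
    scale = abs(np.linalg.det(A - lam_star * eye))
    if scale < 1e-300:
        scale = 1.0

    def perturbed(g: np.ndarray) -> np.ndarray:
        d = np.outer(g, e_k) if structure == "column" else np.outer(e_k, g)
        return A + d - lam_star * eye

    real_target = abs(lam_star.imag) < 1e-12

    def constraint(g: np.ndarray):
        det = np.linalg.det(perturbed(g)) / scale
        # A real target on a real matrix has identically-zero imaginary part;
        # keeping it would make the constraint Jacobian rank-deficient.
        return [det.real] if real_target else [det.real, det.imag]

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        x0 = rng.standard_normal(m) * (0.5 if s else 0.1)
        res = minimize(
            lambda g: float(g @ g), x0,
            jac=lambda g: 2.0 * g,
            constraints=[{"type": "eq", "fun": constraint}],
            method="SLSQP",
            options={"maxiter": 300, "ftol": 1e-14},
        )
        g = res.x
        # Feasibility judged by actual eigenvalue placement, not solver status.
        eig_err = np.min(np.abs(np.linalg.eigvals(perturbed(g) + lam_star * eye)
                                - lam_star))
        if eig_err < 1e-6:
            best = float(np.linalg.norm(g))
            break  # convex problem: the first feasible optimum is global
    if best is None:
        raise RuntimeError("oracle failed to find a feasible perturbation")
    return best


def oracle_ridge(window: np.ndarray, lam: float) -> np.ndarray:
    """Normal-equation ridge estimate via explicit inverse."""
    Z = np.asarray(window, dtype=float)
    X, Y = Z[:, :-1], Z[:, 1:]
    m = Z.shape[0]
    return Y @ X.T @ np.linalg.inv(X @ X.T + lam * np.eye(m))


def random_feasible_gammas(A: np.ndarray, lam_star: complex, k: int,
                           n: int, structure: str = "column",
                           seed: int = 0) -> np.ndarray:
    """Random points on the feasibility set (for minimality spot checks).

    Constructed by sampling random gammas and projecting onto the affine
    constraint set via two Newton-free corrections along the constraint
    normal directions computed by finite differences of the determinant.
    """
    rng = np.random.default_rng(seed)
    m = A.shape[0]
    e_k = np.zeros(m)
    e_k[k] = 1.0
    eye = np.eye(m)
    scale = abs(np.linalg.det(A - lam_star * eye)) or 1.0

    def cons(g):
        d = np.outer(g, e_k) if structure == "column" else np.outer(e_k, g)
        det = np.linalg.det(A + d - lam_star * eye) / scale
        return np.array([det.real, det.imag])

    out = []
    while len(out) < n:
        g = rng.standard_normal(m)
        # Affine constraints: Newton projection converges in one step up to
        # rounding; iterate a few times to be safe.
        ok = False
        for _ in range(8):
            c = cons(g)
            if np.abs(c).max() < 1e-10:
                ok = True
                break
            J = np.empty((2, m))
            h = 1e-6
            for i in range(m):
                gp = g.copy()
                gp[i] += h
                J[:, i] = (cons(gp) - c) / h
            step, *_ = np.linalg.lstsq(J, -c, rcond=None)
            g = g + step
        if ok:
            out.append(g)
    return np.array(out)
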