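"""Inner solvers for weighted-ridge GLM objectives.

All routines minimize the same objective over theta,

    f(theta) = -2 * loglik(y, A @ theta) + sum_j w_j * theta_j**2,

with a per-coordinate nonnegative penalty weight vector ``w``.  Three
strategies are provided:

``newton``
    Damped Newton/IRLS with a dense Hessian solve.  The reference solver for
    small-to-moderate column counts.
``woodbury``
    The same Newton step, but the leading ``dense_block`` columns (all of
    which must carry strictly positive weights) are inverted through the
    matrix-inversion identity so each step costs O(n^2 * p) instead of
    O(p^3).  Exact up to floating point: it solves the identical linear
    system, so results agree with ``newton``.
``cd``
    Cyclic coordinate descent with a per-coordinate trust region, in the
    style of large-scale regularized logistic regression solvers.

Every strategy enforces monotone decrease of ``f`` (Newton via step halving,
coordinate descent via the trust region).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, gammaln

__all__ = ["SolveResult", "FitError", "solve_penalized", "penalized_objective", "loglik"]

_D_FLOOR = 1e-12  # curvature floor for saturated logistic observations


class FitError(RuntimeError):
    """Inner solver failed to converge; carries iteration diagnostics."""

    def __init__(self, message, n_iter=None, max_step=None):
        super().__init__(message)
        self.n_iter = n_iter
        self.max_step = max_step


@dataclasses.dataclass
class SolveResult:
    theta: np.ndarray
    n_iter: int
    converged: bool
    objective: float
    objective_start: float
    loglik: float


def loglik(y, eta, family: str) -> float:
    """Log-likelihood of a linear predictor under the canonical link."""
    if family == "logistic":
        # y*eta - log(1 + exp(eta)), stable for large |eta|
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    if family == "poisson":
        return float(np.sum(y * eta - np.exp(np.minimum(eta, 700.0)) - gammaln(y + 1.0)))
    raise ValueError(f"unknown family {family!r}")


def _mu_d(eta, family):
    """Mean and IRLS curvature for the canonical link."""
    if family == "logistic":
        mu = expit(eta)
        d = np.maximum(mu * (1.0 - mu), _D_FLOOR)
    else:
        mu = np.exp(np.minimum(eta, 700.0))
        d = np.maximum(mu, _D_FLOOR)
    return mu, d


def penalized_objective(y, A, theta, weights, family) -> float:
    eta = A @ theta
    return -2.0 * loglik(y, eta, family) + float(np.sum(weights * theta**2))


def solve_penalized(y, A, weights, family, theta0=None, *,
                    method: str = "newton", dense_block: int = 0,
                    tol: float = 1e-9, max_iter: int = 100) -> SolveResult:
    """Minimize ``-2*loglik + sum w_j theta_j^2`` over theta.

    Parameters
    ----------
    y : (n,) response
    A : (n, q) design
    weights : (q,) nonnegative penalty weights (0 = unpenalized)
    theta0 : warm start, defaults to zeros
    method : "newton" | "woodbury" | "cd"
    dense_block : for "woodbury", the number of leading columns handled via
        the inversion identity; their weights must be strictly positive.
    """
    y = np.asarray(y, dtype=float)
    A = np.asarray(A, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n, q = A.shape
    if weights.shape != (q,):
        raise ValueError("weights length must match design columns")
    theta = np.zeros(q) if theta0 is None else np.asarray(theta0, dtype=float).copy()

    if method == "cd":
        return _solve_cd(y, A, weights, family, theta, tol, max_iter)
    if method not in ("newton", "woodbury"):
        raise ValueError(f"unknown solver method {method!r}")
    if method == "woodbury" and np.any(weights[:dense_block] <= 0):
        raise ValueError("woodbury solver requires positive weights on the dense block")

    f = penalized_objective(y, A, theta, weights, family)
    f_start = f
    converged = False
    it = 0
    max_step = np.inf
    for it in range(1, max_iter + 1):
        eta = A @ theta
        mu, d = _mu_d(eta, family)
        resid = y - mu
        # Newton direction for f/2: (A' D A + diag(w)) delta = A'(y-mu) - w*theta
        rhs_full = A.T @ resid - weights * theta
        if method == "newton" or dense_block == 0:
            H = (A * d[:, None]).T @ A
            H[np.diag_indices_from(H)] += weights
            delta = _chol_solve_sym(H, rhs_full)
        else:
            delta = _woodbury_direction(A, d, weights, rhs_full, dense_block)

        # the undamped Newton step bounds the remaining error near the
        # optimum, so it doubles as the convergence measure
        if float(np.max(np.abs(delta))) < tol:
            converged = True
            break

        # step halving on the true objective; a step is only accepted if it
        # strictly decreases f (Newton directions are descent directions
        # here, so failure to decrease means we sit at the optimum)
        step = 1.0
        for _ in range(60):
            cand = theta + step * delta
            f_new = penalized_objective(y, A, cand, weights, family)
            if f_new < f - 1e-12 * (1.0 + abs(f)):
                break
            step *= 0.5
        else:
            # objective flat to rounding: we are at the optimum to within
            # floating point even though the raw step is above tol
            converged = True
            break
        max_step = float(np.max(np.abs(step * delta))) if step > 0 else 0.0
        theta = cand
        f = f_new
        if max_step < tol:
            converged = True
            break

    if not converged:
        raise FitError(
            f"inner solver did not converge in {max_iter} iterations "
            f"(last max step {max_step:.3e})",
            n_iter=it, max_step=max_step,
        )
    ll = loglik(y, A @ theta, family)
    return SolveResult(theta=theta, n_iter=it, converged=True,
                       objective=f, objective_start=f_start, loglik=ll)


def _chol_solve_sym(H, rhs):
    try:
        c = cho_factor(H, lower=True, check_finite=False)
        return cho_solve(c, rhs, check_finite=False)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * (1.0 + np.trace(H) / H.shape[0])
        H = H + jitter * np.eye(H.shape[0])
        c = cho_factor(H, lower=True, check_finite=False)
        return cho_solve(c, rhs, check_finite=False)


def _woodbury_direction(A, d, weights, rhs, k):
    """Solve (A' D A + diag(w)) delta = rhs with a block-Woodbury scheme.

    The leading ``k`` columns (large penalized block, weights > 0) are
    inverted via the inversion identity against an n x n system; the trailing
    small block is folded in through its Schur complement.
    """
    n = A.shape[0]
    Xb = A[:, :k]
    U = A[:, k:]
    wb = weights[:k]
    wu = weights[k:]
    winv = 1.0 / wb
    sqd = np.sqrt(d)
    Xs = Xb * sqd[:, None]                      # n x k
    M = (Xs * winv) @ Xs.T                      # n x n, cost n^2 k
    M[np.diag_indices_from(M)] += 1.0
    cho = cho_factor(M, lower=True, check_finite=False)

    def K_inv(V):
        # K = Xb' D Xb + diag(wb); returns K^{-1} V for V of shape (k, m)
        Wv = V * (winv[:, None] if V.ndim == 2 else winv)
        T = Xs @ Wv
        S = cho_solve(cho, T, check_finite=False)
        back = Xs.T @ S
        return Wv - (back * (winv[:, None] if V.ndim == 2 else winv))

    rx, ru = rhs[:k], rhs[k:]
    if U.shape[1] == 0:
        return K_inv(rx)
    DU = U * d[:, None]
    Kxu = Xb.T @ DU                             # k x d
    Ki_rx = K_inv(rx)
    Ki_Kxu = K_inv(Kxu)
    S = U.T @ DU - Kxu.T @ Ki_Kxu
    S[np.diag_indices_from(S)] += wu
    delta_u = np.linalg.solve(S, ru - Kxu.T @ Ki_rx)
    delta_b = Ki_rx - Ki_Kxu @ delta_u
    return np.concatenate([delta_b, delta_u])


def _solve_cd(y, A, weights, family, theta, tol, max_iter):
    """Cyclic coordinate descent with per-coordinate trust regions."""
    n, q = A.shape
    eta = A @ theta
    trust = np.ones(q)
    f_start = penalized_objective(y, A, theta, weights, family)
    converged = False
    cycles = 0
    # cyclic descent converges linearly, so its cycle budget is much larger
    # than the Newton iteration budget
    max_cycles = max(max_iter, 50) * 100
    for cycles in range(1, max_cycles + 1):
        max_move = 0.0
        for j in range(q):
            a = A[:, j]
            mu, d = _mu_d(eta, family)
            g = -2.0 * (a @ (y - mu)) + 2.0 * weights[j] * theta[j]
            h = 2.0 * (a * d) @ a + 2.0 * weights[j]
            if h <= 0:
                continue
            move = -g / h
            move = float(np.clip(move, -trust[j], trust[j]))
            if move != 0.0:
                theta[j] += move
                eta = eta + move * a
            trust[j] = max(2.0 * abs(move), trust[j] / 2.0)
            max_move = max(max_move, abs(move))
        if max_move < tol:
            converged = True
            break
    if not converged:
        raise FitError(
            f"coordinate descent did not converge in {max_cycles} cycles",
            n_iter=cycles, max_step=None,
        )
    f = penalized_objective(y, A, theta, weights, family)
    return SolveResult(theta=theta, n_iter=cycles, converged=True,
                       objective=f, objective_start=f_start,
                       loglik=loglik(y, eta, family))
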