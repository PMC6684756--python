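"""Internal Newton (IRLS) solver for (optionally ridge-penalized) logistic
regression.

Minimizes  NLL(beta) + (lambda/2) * sum(beta[1:]**2)  — the intercept
(column 0 of the design matrix) is never penalized.  Kept dependency-light
and allocation-light because leave-pair-out cross-validation and the
bootstrap refit it hundreds of thousands of times on small matrices.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class SeparationError(RuntimeError):
    """Unpenalized fit diverged (perfect or quasi-complete separation)."""


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge_lambda: float = 0.0,
    beta_start: np.ndarray | None = None,
    max_iter: int = 60,
    grad_tol: float = 1e-8,
    diverge_norm: float = 40.0,
) -> tuple[np.ndarray, bool, int]:
    """Newton iterations with step-halving; returns (beta, converged, n_iter).

    Raises :class:`SeparationError` when ``ridge_lambda == 0`` and the
    coefficients diverge or the fit fails to converge — the standard
    symptom of separated data; a small ridge penalty restores a unique
    optimum.
    """
    n, k = X.shape
    beta = np.zeros(k) if beta_start is None else np.array(beta_start, dtype=float)
    pen = np.full(k, float(ridge_lambda))
    pen[0] = 0.0

    def objective(b):
        eta = X @ b
        # log(1 + exp(-|eta|)) + max(0, -s*eta) is the stable NLL piece
        nll = np.sum(np.logaddexp(0.0, eta) - y * eta)
        return nll + 0.5 * np.sum(pen * b * b)

    obj = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        grad = X.T @ (p - y) + pen * beta
        if np.max(np.abs(grad)) < grad_tol * max(1.0, n):
            converged = True
            break
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # backtracking keeps Newton safe far from the optimum
        t = 1.0
        for _ in range(30):
            cand = beta - t * step
            cand_obj = objective(cand)
            if cand_obj <= obj + 1e-12:
                beta, obj = cand, cand_obj
                break
            t *= 0.5
        else:
            break
        if ridge_lambda == 0.0 and np.max(np.abs(beta[1:] if k > 1 else beta)) > diverge_norm:
            raise SeparationError(
                "logistic fit diverging: data appear separated; "
                "set ridge_lambda > 0"
            )
    if not converged:
        p = expit(X @ beta)
        grad = X.T @ (p - y) + pen * beta
        converged = bool(np.max(np.abs(grad)) < 1e-5 * max(1.0, n))
        if not converged and ridge_lambda == 0.0:
            raise SeparationError(
                "logistic fit did not converge (possible separation); "
                "set ridge_lambda > 0"
            )
    return beta, converged, it


def covariance(X: np.ndarray, beta: np.ndarray, ridge_lambda: float = 0.0) -> np.ndarray:
    """Inverse (penalized) observed information; asymptotic covariance."""
    p = expit(X @ beta)
    w = p * (1.0 - p)
    H = (X * w[:, None]).T @ X
    pen = np.full(X.shape[1], float(ridge_lambda))
    pen[0] = 0.0
    H[np.diag_indices_from(H)] += pen
    return np.linalg.inv(H)
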