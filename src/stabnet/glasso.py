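"""Graphical lasso with an entrywise penalty matrix.

Solves, for a symmetric PSD ``S`` and a symmetric nonnegative penalty matrix
``P`` with zero diagonal,

    maximize  log det(Theta) - tr(S Theta) - sum_{i != j} P_ij |Theta_ij|

over symmetric positive-definite ``Theta``.  Diagonal entries are never
penalized.  The solver is proximal gradient with backtracking line search
(monotone in the objective), which keeps the iterates positive-definite and
supports arbitrary per-entry penalties — the ingredient the randomized
stability-selection ensemble needs and which scalar-penalty implementations
do not expose.

The inner loop is numba-compiled when numba is available and falls back to
the identical pure-NumPy code otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ConvergenceError",
    "empirical_covariance",
    "graphical_lasso",
    "glasso_objective",
    "kkt_residual",
]


class ConvergenceError(RuntimeError):
    """Raised when the solver hits max_iter; carries the last duality gap."""

    def __init__(self, message: str, dual_gap: float, last_change: float):
        super().__init__(message)
        self.dual_gap = dual_gap
        self.last_change = last_change


def _chol_logdet(A):
    """Lower Cholesky factor and log-determinant; ok flag False if not PD."""
    p = A.shape[0]
    L = np.zeros((p, p))
    logdet = 0.0
    for j in range(p):
        s = A[j, j]
        for k in range(j):
            s -= L[j, k] * L[j, k]
        if s <= 0.0:
            return L, 0.0, False
        L[j, j] = np.sqrt(s)
        logdet += 2.0 * np.log(L[j, j])
        for i in range(j + 1, p):
            t = A[i, j]
            for k in range(j):
                t -= L[i, k] * L[j, k]
            L[i, j] = t / L[j, j]
    return L, logdet, True


def _penalized_objective(S, P, Theta, logdet):
    p = S.shape[0]
    pen = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                pen += P[i, j] * np.abs(Theta[i, j])
    return logdet - np.trace(S @ Theta) - pen


def _prox_from(S, P, Y, logdet_y):
    """One backtracking proximal-gradient step from PD base point Y.

    Returns (Z, logdet_z, ok).  The sufficient-decrease condition guarantees
    the penalized objective at Z is >= the one at Y.
    """
    Wy = np.linalg.inv(Y)
    fy = -logdet_y + np.trace(S @ Y)
    G = S - Wy
    eigs = np.linalg.eigvalsh(Y)
    step = eigs[0] * eigs[0]  # 1 / ||inv(Y)||_2^2, local Lipschitz step
    for _bt in range(80):
        Z = Y - step * G
        # soft-threshold off-diagonals by step * P (P diagonal is zero)
        Z = np.sign(Z) * np.maximum(np.abs(Z) - step * P, 0.0)
        Z = 0.5 * (Z + Z.T)
        _, logdet_z, ok = _chol_logdet(Z)
        if ok:
            D = Z - Y
            lin = 0.0
            quad = 0.0
            pz = S.shape[0]
            for i in range(pz):
                for j in range(pz):
                    lin += G[i, j] * D[i, j]
                    quad += D[i, j] * D[i, j]
            fz = -logdet_z + np.trace(S @ Z)
            if fz <= fy + lin + quad / (2.0 * step) + 1e-12:
                return Z, logdet_z, True
        step *= 0.5
    return Y, logdet_y, False


def _fista_core(S, P, tol, max_iter):
    """Monotone accelerated proximal gradient (FISTA with fallback).

    Momentum steps are kept only when they do not decrease the penalized
    objective; otherwise a plain proximal step from the current iterate is
    taken (which cannot decrease it), so the recorded objective history is
    non-decreasing.  Returns (Theta, n_iter, last_change, converged, history).
    """
    p = S.shape[0]
    Theta = np.zeros((p, p))
    for i in range(p):
        Theta[i, i] = 1.0 / S[i, i]
    _, logdet, _ = _chol_logdet(Theta)
    F_cur = _penalized_objective(S, P, Theta, logdet)
    history = np.empty(max_iter + 1)
    history[0] = F_cur
    Y = Theta.copy()
    logdet_y = logdet
    t = 1.0
    last_change = np.inf
    n_done = 0
    for it in range(max_iter):
        Z, logdet_z, ok = _prox_from(S, P, Y, logdet_y)
        if ok:
            F_z = _penalized_objective(S, P, Z, logdet_z)
        else:
            F_z = -np.inf
        if F_z < F_cur:  # momentum overshoot (or failure): restart from Theta
            t = 1.0
            Z, logdet_z, ok = _prox_from(S, P, Theta, logdet)
            if not ok:  # cannot improve further at all
                n_done = it
                break
            F_z = _penalized_objective(S, P, Z, logdet_z)
        last_change = np.max(np.abs(Z - Theta))
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Y = Z + ((t - 1.0) / t_new) * (Z - Theta)
        _, logdet_y, ok_y = _chol_logdet(Y)
        if not ok_y:  # extrapolation left the PD cone; restart momentum
            Y = Z.copy()
            logdet_y = logdet_z
            t_new = 1.0
        Theta = Z
        logdet = logdet_z
        F_cur = max(F_cur, F_z)
        t = t_new
        history[it + 1] = F_cur
        n_done = it + 1
        if last_change < tol:
            return Theta, n_done, last_change, True, history[: n_done + 1]
    return Theta, n_done, last_change, False, history[: n_done + 1]


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _chol_logdet = njit(cache=True)(_chol_logdet)
    _penalized_objective = njit(cache=True)(_penalized_objective)
    _prox_from = njit(cache=True)(_prox_from)
    _fista_core = njit(cache=True)(_fista_core)
except ImportError:  # pragma: no cover
    pass


def empirical_covariance(X) -> np.ndarray:
    """Maximum-likelihood (1/n) covariance of the columns of ``X``.

    Accepts an (n, p) array or a :class:`~stabnet.datatypes.DataTable`.
    Missing values are an error: imputation is out of scope.
    """
    if hasattr(X, "values") and not isinstance(X, np.ndarray):
        X = X.values() if callable(X.values) else X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (n >= 2, p) matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing/non-finite values in input (no imputation in scope)")
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / X.shape[0]
    return 0.5 * (S + S.T)


def _validate_penalty(S: np.ndarray, penalty) -> np.ndarray:
    p = S.shape[0]
    P = np.asarray(penalty, dtype=float)
    if P.ndim == 0:  # scalar convenience: broadcast to off-diagonals
        P = np.full((p, p), float(P))
        np.fill_diagonal(P, 0.0)
    if P.shape != S.shape:
        raise ValueError("penalty shape must match S")
    if not np.allclose(P, P.T, atol=1e-12):
        raise ValueError("penalty must be symmetric")
    if np.any(P < 0):
        raise ValueError("penalty must be nonnegative")
    if np.any(np.diag(P) != 0):
        raise ValueError("penalty diagonal must be zero (diagonal is unpenalized)")
    return P


def glasso_objective(S: np.ndarray, penalty, theta: np.ndarray) -> float:
    """Penalized log-likelihood log det(Theta) - tr(S Theta) - sum P|Theta|."""
    P = _validate_penalty(S, penalty)
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    off = np.abs(theta).copy()
    np.fill_diagonal(off, 0.0)
    return float(logdet - np.trace(S @ theta) - np.sum(P * off))


def graphical_lasso(
    S: np.ndarray,
    penalty,
    tol: float = 1e-6,
    max_iter: int = 500,
    return_history: bool = False,
):
    """Estimate a sparse precision matrix from covariance ``S``.

    Parameters
    ----------
    S : (p, p) symmetric PSD covariance.
    penalty : scalar or (p, p) symmetric nonnegative matrix, zero diagonal.
        Per-entry L1 penalties on the off-diagonal precision entries.
    tol : float
        Convergence on the max absolute change between successive iterates.
    max_iter : int
        Iteration budget; exceeding it raises :class:`ConvergenceError`.
    return_history : bool
        Also return the per-iteration penalized objective (non-decreasing).

    Returns
    -------
    theta : (p, p) ndarray — or ``(theta, history)`` if requested.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if np.any(np.diag(S) <= 0):
        raise ValueError("S must have positive diagonal")
    P = _validate_penalty(S, penalty)

    theta, n_iter, last_change, converged, history = _fista_core(
        S, P, float(tol), int(max_iter)
    )
    if not converged:
        gap = _dual_gap(S, P, theta)
        raise ConvergenceError(
            f"graphical lasso did not converge in {max_iter} iterations "
            f"(last max change {last_change:.3g}, duality gap {gap:.3g})",
            dual_gap=gap,
            last_change=float(last_change),
        )
    theta = 0.5 * (theta + theta.T)
    if return_history:
        return theta, np.asarray(history)
    return theta


def _dual_gap(S: np.ndarray, P: np.ndarray, theta: np.ndarray) -> float:
    # At the optimum tr(S Theta) - p + sum_{i!=j} P|Theta_ij| = 0.
    off = np.abs(theta).copy()
    np.fill_diagonal(off, 0.0)
    return float(np.trace(S @ theta) - S.shape[0] + np.sum(P * off))


def kkt_residual(S: np.ndarray, penalty, theta: np.ndarray, zero_tol: float = 1e-8) -> float:
    """Max violation of the stationarity conditions; ~0 at the optimum.

    For W = Theta^{-1}: diagonal requires W_ii = S_ii; nonzero off-diagonals
    require S_ij - W_ij + P_ij sign(Theta_ij) = 0; zero entries require
    |S_ij - W_ij| <= P_ij.
    """
    P = _validate_penalty(S, penalty)
    W = np.linalg.inv(theta)
    p = S.shape[0]
    worst = 0.0
    for i in range(p):
        worst = max(worst, abs(S[i, i] - W[i, i]))
        for j in range(p):
            if i == j:
                continue
            r = S[i, j] - W[i, j]
            if abs(theta[i, j]) > zero_tol:
                worst = max(worst, abs(r + P[i, j] * np.sign(theta[i, j])))
            else:
                worst = max(worst, max(0.0, abs(r) - P[i, j]))
    return worst
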