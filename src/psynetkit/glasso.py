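"""Sparse inverse-covariance estimation by the graphical lasso.

Block coordinate-descent solver for

    max_K  log det K - tr(S K) - lam * sum_{i != j} |K_ij|

with the l1 penalty on off-diagonal precision entries only (the diagonal
is unpenalized, so the fitted covariance keeps ``W_ii = S_ii``).  The
solver sweeps nodes, solving each node's lasso subproblem by coordinate
descent on the regression coefficients, and warm-starts across calls —
which is what makes dense :math:`\\lambda`-path fits and permutation
refits affordable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glasso", "GlassoNotConverged"]


class GlassoNotConverged(RuntimeError):
    """Raised when coordinate descent fails to reach tolerance.

    Carries the final relative-change metric in ``args[1]``.
    """


@njit(cache=True)
def _glasso_cd(S, lam, W, B, tol, max_iter, inner_tol, inner_max):  # pragma: no cover - jit
    p = S.shape[0]
    # unpenalized diagonal: W_jj fixed at S_jj
    for j in range(p):
        W[j, j] = S[j, j]
    delta = np.inf
    # scale for the outer convergence test
    off_scale = 0.0
    cnt = 0
    for i in range(p):
        for j in range(p):
            if i != j:
                off_scale += abs(S[i, j])
                cnt += 1
    off_scale = off_scale / cnt if cnt > 0 else 1.0
    if off_scale <= 0.0:
        off_scale = 1.0
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        delta = 0.0
        for j in range(p):
            beta = B[:, j]
            # lasso subproblem on node j by coordinate descent
            for _inner in range(inner_max):
                inner_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    # partial residual for coordinate k
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * beta[l]
                    old = beta[k]
                    if r > lam:
                        new = (r - lam) / W[k, k]
                    elif r < -lam:
                        new = (r + lam) / W[k, k]
                    else:
                        new = 0.0
                    beta[k] = new
                    d = abs(new - old)
                    if d > inner_delta:
                        inner_delta = d
                if inner_delta < inner_tol:
                    break
            # update W column j: w12 = W11 @ beta
            for k in range(p):
                if k == j:
                    continue
                w = 0.0
                for l in range(p):
                    if l != j:
                        w += W[k, l] * beta[l]
                d = abs(w - W[k, j])
                if d > delta:
                    delta = d
                W[k, j] = w
                W[j, k] = w
        if delta < tol * off_scale:
            break
    # recover the precision matrix from W and the regression coefficients
    K = np.zeros((p, p))
    for j in range(p):
        denom = W[j, j]
        for l in range(p):
            if l != j:
                denom -= W[l, j] * B[l, j]
        kjj = 1.0 / denom
        K[j, j] = kjj
        for l in range(p):
            if l != j:
                K[l, j] = -B[l, j] * kjj
    # symmetrize (the two node-wise estimates of K_ij agree at convergence)
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    return K, n_iter, delta / off_scale


def glasso(
    S: np.ndarray,
    lam: float,
    *,
    tol: float = 1e-6,
    max_iter: int = 200,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
    raise_on_nonconvergence: bool = True,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Solve the graphical lasso at penalty ``lam``.

    Parameters
    ----------
    S
        Symmetric sample covariance/correlation matrix.
    lam
        Nonnegative l1 penalty on off-diagonal precision entries.
    tol
        Outer convergence tolerance, relative to the mean absolute
        off-diagonal of ``S``.
    warm
        Optional ``(W, B)`` state from a previous call (e.g. the next
        point on a lambda path); arrays are copied before use.

    Returns
    -------
    (precision, covariance, state)
        ``precision`` is symmetric positive definite, ``covariance`` its
        fitted inverse with ``W_ii = S_ii``; ``state`` can be passed as
        ``warm`` to the next call.
    """
    S = np.asarray(S, dtype=np.float64)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be square and symmetric")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if lam == 0.0:
        # unpenalized MLE: direct inversion
        K = np.linalg.inv(S)
        K = 0.5 * (K + K.T)
        W = S.copy()
        B = _betas_from_precision(K)
        return K, W, (W, B)
    if warm is not None:
        W = np.array(warm[0], dtype=np.float64, copy=True)
        B = np.array(warm[1], dtype=np.float64, copy=True)
    else:
        W = S.copy()
        B = np.zeros((p, p))
    K, n_iter, rel_delta = _glasso_cd(
        S, float(lam), W, B, float(tol), int(max_iter), float(tol) * 0.1, 1000
    )
    if rel_delta >= tol and n_iter >= max_iter and raise_on_nonconvergence:
        raise GlassoNotConverged(
            f"graphical lasso did not converge in {max_iter} sweeps "
            f"(relative change {rel_delta:.3e} >= tol {tol:.1e})",
            rel_delta,
        )
    return K, W, (W, B)


def _betas_from_precision(K: np.ndarray) -> np.ndarray:
    """Nodewise regression coefficients implied by a precision matrix."""
    p = K.shape[0]
    B = np.zeros((p, p))
    for j in range(p):
        mask = np.arange(p) != j
        B[mask, j] = -K[mask, j] / K[j, j]
    return B
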