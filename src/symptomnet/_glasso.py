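"""Blockwise coordinate-descent graphical lasso kernel.

Maximizes  log det(Theta) - tr(S Theta) - lam * sum_{i != j} |Theta_ij|
over symmetric positive-definite Theta (L1 penalty on off-diagonals only),
using the classical covariance-update algorithm: cycle over nodes, solve each
node's lasso subproblem by coordinate descent, and update the working
covariance W column by column. With an off-diagonal-only penalty the diagonal
of W stays fixed at diag(S).

The kernel is numba-compiled because the surrounding pipeline (bootstrap
resampling, case-dropping stability, permutation network comparison) refits
the whole regularization path tens of thousands of times on 16-node inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def glasso_kernel(S, lam, thresh, max_sweeps, W, Theta, B):  # pragma: no cover
    """One glasso solve. W and B act as warm starts and are updated in place.

    ``thresh`` is the absolute convergence threshold on the maximum change of
    the working covariance per sweep. Returns (converged, sweeps, last_change).
    """
    p = S.shape[0]
    for i in range(p):
        W[i, i] = S[i, i]
    delta = 0.0
    sweeps = 0
    for sweep in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            # lasso subproblem: min_b 0.5 b'W11 b - s12'b + lam|b|_1
            for _inner in range(1000):
                inner_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for m in range(p):
                        if m == j or m == k:
                            continue
                        r -= W[k, m] * B[m, j]
                    old = B[k, j]
                    if r > lam:
                        new = (r - lam) / W[k, k]
                    elif r < -lam:
                        new = (r + lam) / W[k, k]
                    else:
                        new = 0.0
                    if new != old:
                        B[k, j] = new
                        d = abs(new - old)
                        if d > inner_delta:
                            inner_delta = d
                if inner_delta < 0.1 * thresh:
                    break
            for k in range(p):
                if k == j:
                    continue
                acc = 0.0
                for m in range(p):
                    if m == j:
                        continue
                    acc += W[k, m] * B[m, j]
                d = abs(acc - W[k, j])
                if d > delta:
                    delta = d
                W[k, j] = acc
                W[j, k] = acc
        sweeps = sweep + 1
        if delta < thresh:
            break
    # recover the precision matrix from (W, B)
    for j in range(p):
        acc = W[j, j]
        for m in range(p):
            if m != j:
                acc -= W[m, j] * B[m, j]
        tjj = 1.0 / acc
        Theta[j, j] = tjj
        for m in range(p):
            if m != j:
                Theta[m, j] = -B[m, j] * tjj
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (Theta[i, j] + Theta[j, i])
            Theta[i, j] = v
            Theta[j, i] = v
    return delta < thresh, sweeps, delta


def glasso_objective(theta: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Penalized log-likelihood value (the quantity the kernel maximizes)."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    penalty = lam * (np.abs(theta).sum() - np.trace(np.abs(theta)))
    return logdet - float(np.sum(S * theta)) - penalty
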