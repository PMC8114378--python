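"""Restricted Gaussian MLE of a precision matrix (covariance selection).

Block-coordinate algorithm: cycle over nodes, regressing each node on
its support neighbors within the working covariance W, until W
stabilizes. At the solution ``W_ij = S_ij`` on the support and diagonal
while ``(W^-1)_ij = 0`` off the support. A numba-compiled kernel is
used when available; a numpy implementation is the fallback.
"""

from __future__ import annotations

import numpy as np


def _refit_core_numpy(
    s: np.ndarray, support: np.ndarray, max_iter: int, tol: float
) -> np.ndarray:
    p = s.shape[0]
    w = s.copy()
    betas = [np.zeros(p - 1) for _ in range(p)]
    others_idx = [np.array([i for i in range(p) if i != j]) for j in range(p)]
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            others = others_idx[j]
            nbr = np.where(support[others, j])[0]
            beta_full = np.zeros(p - 1)
            if len(nbr):
                w11 = w[np.ix_(others, others)]
                beta = np.linalg.solve(w11[np.ix_(nbr, nbr)], s[others[nbr], j])
                beta_full[nbr] = beta
                w12 = w11 @ beta_full
            else:
                w12 = np.zeros(p - 1)
            delta = max(delta, np.abs(w[others, j] - w12).max())
            w[others, j] = w12
            w[j, others] = w12
            betas[j] = beta_full
        if delta < tol:
            break
    theta = np.zeros((p, p))
    for j in range(p):
        others = others_idx[j]
        t_jj = 1.0 / (s[j, j] - w[others, j] @ betas[j])
        theta[j, j] = t_jj
        theta[others, j] = -betas[j] * t_jj
    return theta


try:
    from numba import njit

    @njit(cache=True)
    def _refit_core_jit(s, support, max_iter, tol):  # pragma: no cover - jit
        p = s.shape[0]
        w = s.copy()
        betas = np.zeros((p, p))
        for _ in range(max_iter):
            delta = 0.0
            for j in range(p):
                k = 0
                for i in range(p):
                    if i != j and support[i, j]:
                        k += 1
                if k > 0:
                    nbr = np.empty(k, dtype=np.int64)
                    m = 0
                    for i in range(p):
                        if i != j and support[i, j]:
                            nbr[m] = i
                            m += 1
                    a = np.empty((k, k))
                    b = np.empty(k)
                    for x in range(k):
                        b[x] = s[nbr[x], j]
                        for y in range(k):
                            a[x, y] = w[nbr[x], nbr[y]]
                    beta = np.linalg.solve(a, b)
                    for i in range(p):
                        betas[j, i] = 0.0
                    for x in range(k):
                        betas[j, nbr[x]] = beta[x]
                    for i in range(p):
                        if i == j:
                            continue
                        w12 = 0.0
                        for x in range(k):
                            w12 += w[i, nbr[x]] * beta[x]
                        d = abs(w[i, j] - w12)
                        if d > delta:
                            delta = d
                        w[i, j] = w12
                        w[j, i] = w12
                else:
                    for i in range(p):
                        betas[j, i] = 0.0
                        if i != j:
                            d = abs(w[i, j])
                            if d > delta:
                                delta = d
                            w[i, j] = 0.0
                            w[j, i] = 0.0
            if delta < tol:
                break
        theta = np.zeros((p, p))
        for j in range(p):
            dot = 0.0
            for i in range(p):
                if i != j:
                    dot += w[i, j] * betas[j, i]
            t_jj = 1.0 / (s[j, j] - dot)
            theta[j, j] = t_jj
            for i in range(p):
                if i != j:
                    theta[i, j] = -betas[j, i] * t_jj
        return theta

    def _refit_core(s, support, max_iter, tol):
        return _refit_core_jit(
            np.ascontiguousarray(s), np.ascontiguousarray(support), max_iter, tol
        )

except ImportError:  # pragma: no cover - numba always present in practice
    _refit_core = _refit_core_numpy


def refit_mle(
    s: np.ndarray, support: np.ndarray, max_iter: int = 100, tol: float = 1e-7
) -> np.ndarray:
    """Gaussian MLE of the precision matrix restricted to a zero pattern.

    ``support`` is a boolean adjacency (off-diagonal zero pattern). Used
    to score candidate supports with an unshrunken (relaxed) likelihood
    and to debias the finally selected network.
    """
    p = s.shape[0]
    support = np.asarray(support, dtype=bool)
    if support.sum() == 0:
        return np.diag(1.0 / np.diag(s))
    if (support | np.eye(p, dtype=bool)).all():
        return np.linalg.inv(s)
    theta = _refit_core(np.asarray(s, dtype=float), support, max_iter, tol)
    theta = (theta + theta.T) / 2
    theta[~support & ~np.eye(p, dtype=bool)] = 0.0
    return theta
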