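"""Sparse partial-correlation network estimation.

Single networks are estimated by L1-penalized Gaussian maximum
likelihood (graphical lasso) with the penalty selected by the Extended
Bayesian Information Criterion,

    EBIC(lambda) = -2 logL + E log n + 4 gamma E log p,

where E is the number of nonzero off-diagonal pairs of the estimated
precision matrix. Two group networks can be estimated jointly with the
Fused Graphical Lasso, which adds an L1 fusion penalty on between-group
differences of precision entries and is solved here by ADMM with a
closed-form fusion proximal step for two groups.

Partial correlations are recovered from the selected precision matrix
Theta as ``rho_ij = -theta_ij / sqrt(theta_ii * theta_jj)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

try:  # lean solver entry point, skips per-call parameter validation
    from sklearn.covariance._graph_lasso import _graphical_lasso as _sk_glasso_core

    def _sk_graphical_lasso_path(s, alpha, cov_init=None, max_iter=100, tol=1e-4):
        return _sk_glasso_core(
            s, alpha, cov_init=cov_init, mode="cd", tol=tol, enet_tol=1e-4,
            max_iter=max_iter, verbose=False, eps=np.finfo(np.float64).eps,
        )
except ImportError:  # pragma: no cover - private API moved

    def _sk_graphical_lasso_path(s, alpha, cov_init=None, max_iter=100, tol=1e-4):
        return _sk_graphical_lasso(s, alpha=alpha, max_iter=max_iter, tol=tol)

from ._refit import refit_mle
from .dataset import BeliefDataset
from .network import EDGE_EPS, WeightedNetwork
from .synthetic import partial_corr_from_precision

logger = logging.getLogger(__name__)

__all__ = [
    "EstimationConfig",
    "correlation_matrix",
    "glasso",
    "ebic",
    "ebic_select",
    "ebic_select_from_corr",
    "fused_glasso",
]


@dataclass
class EstimationConfig:
    """Tuning parameters for network estimation.

    ``lambda_grid``, when given, must be strictly positive and increasing;
    otherwise ``n_lambda`` log-spaced values from ``0.01*lambda_max`` to
    ``lambda_max`` are used (``lambda_max`` = largest absolute
    off-diagonal correlation, the smallest penalty giving an empty graph).
    """

    correlation_method: str = "pearson"
    lambda_grid: np.ndarray | None = None
    ebic_gamma: float = 0.5
    n_lambda: int = 100
    refit: bool = True
    early_stop: bool = True
    fgl_lambda1: float = 0.1
    fgl_lambda2: float = 0.05

    def __post_init__(self) -> None:
        if self.correlation_method not in ("pearson", "spearman", "polychoric_auto"):
            raise ValueError(f"unknown correlation method {self.correlation_method!r}")
        if self.ebic_gamma < 0:
            raise ValueError("ebic_gamma must be >= 0")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
                raise ValueError("lambda_grid must be strictly positive and increasing")
            self.lambda_grid = grid

    def grid_for(self, s: np.ndarray) -> np.ndarray:
        if self.lambda_grid is not None:
            return self.lambda_grid
        lam_max = np.abs(s - np.diag(np.diag(s))).max()
        if lam_max <= 0:
            lam_max = 1e-2
        return np.geomspace(0.01 * lam_max, lam_max, self.n_lambda)


# ---------------------------------------------------------------------------
# correlation input
# ---------------------------------------------------------------------------


def _polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric correlation for two ordinal variables."""
    xc = np.unique(x)
    yc = np.unique(y)
    # thresholds from marginal cumulative proportions
    tx = stats.norm.ppf(np.cumsum([np.mean(x == c) for c in xc])[:-1])
    ty = stats.norm.ppf(np.cumsum([np.mean(y == c) for c in yc])[:-1])
    tx = np.concatenate([[-np.inf], tx, [np.inf]])
    ty = np.concatenate([[-np.inf], ty, [np.inf]])
    counts = np.zeros((len(xc), len(yc)))
    for i, cx in enumerate(xc):
        for j, cy in enumerate(yc):
            counts[i, j] = np.sum((x == cx) & (y == cy))

    def neg_loglik(rho: float) -> float:
        cdf = np.zeros((len(tx), len(ty)))
        for i, a in enumerate(tx):
            for j, b in enumerate(ty):
                if np.isinf(a) and a < 0 or np.isinf(b) and b < 0:
                    cdf[i, j] = 0.0
                elif np.isinf(a) and np.isinf(b):
                    cdf[i, j] = 1.0
                elif np.isinf(a):
                    cdf[i, j] = stats.norm.cdf(b)
                elif np.isinf(b):
                    cdf[i, j] = stats.norm.cdf(a)
                else:
                    cdf[i, j] = stats.multivariate_normal.cdf(
                        [a, b], mean=[0, 0], cov=[[1, rho], [rho, 1]]
                    )
        cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
        cell = np.clip(cell, 1e-12, None)
        return -np.sum(counts * np.log(cell))

    res = minimize_scalar(neg_loglik, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def _polyserial_pair(cont: np.ndarray, ordi: np.ndarray) -> float:
    """Two-step polyserial correlation (Olsson-Drasgow-Dorans estimator)."""
    cats = np.unique(ordi)
    tau = stats.norm.ppf(np.cumsum([np.mean(ordi == c) for c in cats])[:-1])
    r = np.corrcoef(cont, ordi)[0, 1]
    sd_codes = ordi.std(ddof=0)
    est = r * sd_codes / np.sum(stats.norm.pdf(tau))
    return float(np.clip(est, -0.999, 0.999))


def _nearest_psd_correlation(s: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(s)
    if vals.min() >= 1e-10:
        return s
    vals = np.clip(vals, 1e-8, None)
    s2 = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(s2))
    s2 = s2 / np.outer(d, d)
    np.fill_diagonal(s2, 1.0)
    return (s2 + s2.T) / 2


def correlation_matrix(data: BeliefDataset, method: str = "pearson") -> np.ndarray:
    """Item correlation matrix feeding the partial-correlation estimator.

    ``pearson``/``spearman`` operate on the numeric codes of all columns.
    ``polychoric_auto`` uses polychoric correlations between ordinal or
    binary pairs, polyserial between mixed pairs, and Pearson between
    continuous pairs, with a projection to the nearest positive
    semidefinite correlation matrix if latent-correlation estimation
    breaks PSD.
    """
    x = data.to_numpy()
    n, p = x.shape
    if n <= p:
        warnings.warn(
            f"n={n} <= p={p}: correlation matrix may be singular", stacklevel=2
        )
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [data.var_names[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance column(s): {bad}")

    if method == "pearson":
        s = np.corrcoef(x, rowvar=False)
    elif method == "spearman":
        s = stats.spearmanr(x).statistic
        if np.ndim(s) == 0:  # p == 2
            s = np.array([[1.0, float(s)], [float(s), 1.0]])
    elif method == "polychoric_auto":
        kinds = [data.var_kinds[v] for v in data.var_names]
        s = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                ki, kj = kinds[i], kinds[j]
                if ki == "continuous" and kj == "continuous":
                    r = np.corrcoef(x[:, i], x[:, j])[0, 1]
                elif ki == "continuous":
                    r = _polyserial_pair(x[:, i], x[:, j])
                elif kj == "continuous":
                    r = _polyserial_pair(x[:, j], x[:, i])
                else:
                    r = _polychoric_pair(x[:, i], x[:, j])
                s[i, j] = s[j, i] = r
        s = _nearest_psd_correlation(s)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    s = np.clip((s + s.T) / 2, -1.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return s


# ---------------------------------------------------------------------------
# graphical lasso + EBIC
# ---------------------------------------------------------------------------


def glasso(s: np.ndarray, n: int, lam: float) -> tuple[np.ndarray, float]:
    """L1-penalized precision estimate and Gaussian log-likelihood.

    Minimizes ``-logdet Theta + tr(S Theta) + lam * ||Theta||_1,off``.
    At ``lam = 0`` the solution is the direct inverse of S (S must be
    invertible). Returns ``(precision, logL)`` with
    ``logL = (n/2) (logdet Theta - tr(S Theta))``.
    """
    s = np.asarray(s, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        theta = np.linalg.inv(s)
    else:
        try:
            with warnings.catch_warnings():
                # near-converged fits (tiny residual duality gap) are fine
                warnings.filterwarnings("ignore", message=".*graphical_lasso.*")
                _, theta = _sk_graphical_lasso(s, alpha=lam, max_iter=100, tol=1e-4)
        except FloatingPointError as exc:  # pragma: no cover - rare
            raise RuntimeError(f"graphical lasso failed to converge: {exc}") from exc
    theta = (theta + theta.T) / 2
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise RuntimeError("estimated precision matrix is not positive definite")
    loglik = 0.5 * n * (logdet - np.trace(s @ theta))
    return theta, float(loglik)


def _edge_count(theta: np.ndarray) -> int:
    iu = np.triu_indices(theta.shape[0], k=1)
    return int(np.sum(np.abs(theta[iu]) > EDGE_EPS))


def ebic(loglik: float, theta: np.ndarray, n: int, gamma: float) -> float:
    """Extended BIC: -2 logL + E log n + 4 gamma E log p."""
    e = _edge_count(theta)
    p = theta.shape[0]
    return -2.0 * loglik + e * np.log(n) + 4.0 * gamma * e * np.log(p)


def _network_from_precision(
    theta: np.ndarray, labels: list[str], meta: dict
) -> WeightedNetwork:
    rho = partial_corr_from_precision(theta)
    rho[np.abs(rho) < EDGE_EPS] = 0.0
    return WeightedNetwork(rho, labels, meta)


def ebic_select(
    data: BeliefDataset, config: EstimationConfig | None = None
) -> WeightedNetwork:
    """Estimate a sparse partial-correlation network, tuning by EBIC.

    Fits the graphical lasso over the penalty grid, scores every fit with
    the EBIC at ``config.ebic_gamma``, and returns the winning network
    (ties broken toward the larger, sparser penalty). The selected
    lambda, gamma, correlation method and sparsity are recorded in
    ``meta``.
    """
    config = config or EstimationConfig()
    s = correlation_matrix(data, config.correlation_method)
    return ebic_select_from_corr(s, data.n, data.var_names, config)


def ebic_select_from_corr(
    s: np.ndarray, n: int, labels: list[str], config: EstimationConfig | None = None
) -> WeightedNetwork:
    """EBIC-tuned graphical lasso on a precomputed correlation matrix.

    Fast path for resampling loops (bootstrap, permutation test) where
    the correlation matrix is recomputed cheaply per replicate.
    """
    config = config or EstimationConfig()
    grid = config.grid_for(s)
    best: tuple[float, float, np.ndarray] | None = None
    n_failed = 0
    cov_init = None  # warm start along the penalty path (sparse -> dense)
    seen_supports: set[bytes] = set()
    eye = np.eye(s.shape[0], dtype=bool)
    since_best = 0
    for lam in grid[::-1]:  # dense fits last; ties keep the sparser fit
        try:
            if lam == 0:
                theta, ll = glasso(s, n, 0.0)
            else:
                # with refit, path fits only pin down the support, so a
                # looser solve suffices; magnitudes come from the refit
                path_tol = 1e-3 if config.refit else 1e-4
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cov, theta, *_ = _sk_graphical_lasso_path(
                        s, alpha=float(lam), cov_init=cov_init,
                        max_iter=100, tol=path_tol,
                    )
                cov_init = cov
                theta = (theta + theta.T) / 2
            if config.refit:
                support = (np.abs(theta) > EDGE_EPS) & ~eye
                key = np.packbits(support).tobytes()
                if key in seen_supports:
                    continue  # same candidate model, same score
                seen_supports.add(key)
                theta = refit_mle(s, support)
            sign, logdet = np.linalg.slogdet(theta)
            if sign <= 0:
                raise RuntimeError("precision estimate not positive definite")
            ll = 0.5 * n * (logdet - np.trace(s @ theta))
        except (RuntimeError, FloatingPointError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        score = ebic(ll, theta, n, config.ebic_gamma)
        if best is None or score < best[0] - 1e-12:
            best = (score, float(lam), theta)
            since_best = 0
        else:
            # EBIC along the sparse-to-dense path is in practice
            # unimodal; stop after several non-improving candidates
            since_best += 1
            if config.early_stop and config.refit and since_best >= 3:
                break
    if best is None:
        raise RuntimeError(f"all {len(grid)} graphical lasso fits failed")
    score, lam, theta = best
    meta = {
        "lambda": lam,
        "ebic": score,
        "ebic_gamma": config.ebic_gamma,
        "correlation_method": config.correlation_method,
        "n": n,
        "n_lambda": len(grid),
        "n_failed_fits": n_failed,
    }
    return _network_from_precision(theta, labels, meta)


# ---------------------------------------------------------------------------
# fused graphical lasso (two groups, ADMM)
# ---------------------------------------------------------------------------


def _fused_prox_pair(
    a1: np.ndarray, a2: np.ndarray, l1: float, l2: float, offdiag: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form prox of l1*(|z1|+|z2|) + l2*|z1-z2| (off-diagonals only).

    For two groups the fusion step decouples elementwise: shrink the
    difference toward equality, then soft-threshold each entry.
    """
    diff = a1 - a2
    shift = np.minimum(np.abs(diff) / 2.0, l2) * np.sign(diff)
    z1 = a1 - shift
    z2 = a2 + shift
    z1s = np.sign(z1) * np.maximum(np.abs(z1) - l1, 0.0)
    z2s = np.sign(z2) * np.maximum(np.abs(z2) - l1, 0.0)
    z1 = np.where(offdiag, z1s, z1)
    z2 = np.where(offdiag, z2s, z2)
    return z1, z2


def _theta_update(s: np.ndarray, a: np.ndarray, rho_over_n: float) -> np.ndarray:
    """argmin -logdet T + tr(S T) + (rho/2n)||T - A||_F^2, by eigendecomposition."""
    m = rho_over_n * a - s
    vals, vecs = np.linalg.eigh((m + m.T) / 2)
    d = (vals + np.sqrt(vals**2 + 4.0 * rho_over_n)) / (2.0 * rho_over_n)
    return vecs @ np.diag(d) @ vecs.T


def fused_glasso(
    s1: np.ndarray,
    s2: np.ndarray,
    n1: int,
    n2: int,
    lambda1: float,
    lambda2: float,
    node_labels: list[str] | None = None,
    weight_by_n: bool = True,
    rho: float = 1.0,
    max_iter: int = 1000,
    abs_tol: float = 1e-5,
    rel_tol: float = 1e-4,
) -> tuple[WeightedNetwork, WeightedNetwork]:
    """Jointly estimate two group networks with a fusion penalty.

    Solves, by ADMM,

        min sum_k n_k (-logdet Theta_k + tr(S_k Theta_k))
            + lambda1 sum_k sum_{i != j} |theta_k,ij|
            + lambda2 sum_{i,j} |theta_1,ij - theta_2,ij|

    so ``lambda2 = 0`` reduces to independent graphical lasso fits and a
    very large ``lambda2`` forces the two precision matrices equal. With
    ``weight_by_n=False`` both likelihood terms get weight 1.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("the two groups must share one node set")
    p = s1.shape[0]
    if node_labels is None:
        node_labels = [f"item{i + 1:02d}" for i in range(p)]
    w1, w2 = (float(n1), float(n2)) if weight_by_n else (1.0, 1.0)

    offdiag = ~np.eye(p, dtype=bool)
    theta1 = np.linalg.inv(s1 + 0.1 * np.eye(p))
    theta2 = np.linalg.inv(s2 + 0.1 * np.eye(p))
    z1, z2 = theta1.copy(), theta2.copy()
    u1 = np.zeros((p, p))
    u2 = np.zeros((p, p))

    for it in range(max_iter):
        theta1 = _theta_update(s1, z1 - u1, rho / w1)
        theta2 = _theta_update(s2, z2 - u2, rho / w2)
        z1_old, z2_old = z1, z2
        z1, z2 = _fused_prox_pair(
            theta1 + u1, theta2 + u2, lambda1 / rho, lambda2 / rho, offdiag
        )
        u1 = u1 + theta1 - z1
        u2 = u2 + theta2 - z2

        r_norm = np.sqrt(
            np.linalg.norm(theta1 - z1) ** 2 + np.linalg.norm(theta2 - z2) ** 2
        )
        s_norm = rho * np.sqrt(
            np.linalg.norm(z1 - z1_old) ** 2 + np.linalg.norm(z2 - z2_old) ** 2
        )
        scale = max(
            np.sqrt(np.linalg.norm(theta1) ** 2 + np.linalg.norm(theta2) ** 2),
            np.sqrt(np.linalg.norm(z1) ** 2 + np.linalg.norm(z2) ** 2),
        )
        eps_pri = abs_tol * p * 2 + rel_tol * scale
        eps_dual = abs_tol * p * 2 + rel_tol * rho * np.sqrt(
            np.linalg.norm(u1) ** 2 + np.linalg.norm(u2) ** 2
        )
        if r_norm < eps_pri and s_norm < eps_dual:
            break
        # standard adaptive penalty: keep primal and dual residuals balanced
        if r_norm > 10 * s_norm:
            rho *= 2.0
            u1 /= 2.0
            u2 /= 2.0
        elif s_norm > 10 * r_norm:
            rho /= 2.0
            u1 *= 2.0
            u2 *= 2.0
    else:
        raise RuntimeError(
            f"fused graphical lasso ADMM did not converge in {max_iter} iterations "
            f"(primal residual {r_norm:.3g}, dual residual {s_norm:.3g})"
        )

    meta = {
        "method": "fused_glasso",
        "lambda1": lambda1,
        "lambda2": lambda2,
        "weight_by_n": weight_by_n,
        "n_iter": it + 1,
    }
    # Z carries the exact sparsity pattern from the proximal step
    z1 = np.where(np.abs(z1) > EDGE_EPS, z1, 0.0)
    z2 = np.where(np.abs(z2) > EDGE_EPS, z2, 0.0)
    np.fill_diagonal(z1, np.diag(theta1))
    np.fill_diagonal(z2, np.diag(theta2))
    net1 = _network_from_precision(z1, node_labels, {**meta, "group": 0, "n": n1})
    net2 = _network_from_precision(z2, node_labels, {**meta, "group": 1, "n": n2})
    return net1, net2
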