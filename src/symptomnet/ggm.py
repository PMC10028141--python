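"""Regularized Gaussian graphical model estimation with EBIC selection.

The estimator maximizes the penalized Gaussian log-likelihood

    log det K − trace(S·K) − λ · Σ_{i≠j} |κ_ij|

over positive-definite precision matrices K (diagonal unpenalized by
default), using the classical block coordinate-descent graphical lasso:
each column update solves an L1-penalized regression on the current
covariance estimate W by coordinate descent.  Convergence is declared
when the largest change in W over a full sweep falls below
``convergence_tol``; non-convergence raises with iteration diagnostics.

Model selection fits a descending log-spaced λ path from
λ_max = max off-diagonal |S| and picks the fit minimizing the Extended
Bayesian Information Criterion

    EBIC = −2l + E·log n + 4·E·γ·log p,
    l = (n/2)(log det K − trace(S·K)),

with ties broken toward larger λ (the sparser model).  E counts
nonzero upper-triangle partial correlations after numerical-zero
cleaning (|w| < 1e−7 set to exact zero — coordinate descent leaves
dust).  The log-likelihood drops additive constants, so EBIC values are
comparable only within one dataset.

Edge weights are partial correlations, w_ij = −κ_ij / sqrt(κ_ii·κ_jj).

The inner solver is numba-jitted: the permutation and bootstrap stages
re-estimate the full path tens of thousands of times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .association import AssociationMatrix, correlation_matrix
from .datasets import Network, SymptomDataset, ValidationError

__all__ = [
    "ConvergenceError",
    "GlassoConfig",
    "GGMFit",
    "glasso_fit",
    "lambda_path",
    "select_network",
    "global_strength",
    "partials_from_precision",
    "ebic",
]

#: |w| below this is a structural zero when counting edges
ZERO_TOL = 1e-7


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries iteration diagnostics."""

    def __init__(self, message: str, n_sweeps: int, max_delta: float):
        super().__init__(f"{message} (sweeps={n_sweeps}, last max change={max_delta:.3e})")
        self.n_sweeps = n_sweeps
        self.max_delta = max_delta


@dataclass(frozen=True)
class GlassoConfig:
    """Solver and EBIC-selection settings."""

    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    gamma: float = 0.5
    penalize_diagonal: bool = False
    convergence_tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.n_lambdas < 1:
            raise ValidationError("n_lambdas must be >= 1")
        if not 0.0 < self.lambda_min_ratio <= 1.0:
            raise ValidationError("lambda_min_ratio must lie in (0, 1]")
        if self.gamma < 0.0:
            raise ValidationError("gamma must be >= 0")


@dataclass
class GGMFit:
    """One fitted GGM: precision matrix, partial-correlation network, EBIC."""

    precision: np.ndarray
    network: Network
    lambda_: float
    loglik: float
    edge_count: int
    ebic: float
    n: int
    n_sweeps: int = 0
    #: per-λ selection path (lambda, loglik, edge_count, ebic); filled by select_network
    path: np.ndarray | None = None


@njit(cache=True)
def _glasso_cd(S, lam, W, B, tol, max_iter, inner_max):  # pragma: no cover - jitted
    p = S.shape[0]
    n_sweeps = 0
    max_delta = 0.0
    converged = False
    for sweep in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            # inner lasso: minimize 0.5 b'W11 b - b's12 + lam|b|_1
            for _ in range(inner_max):
                dmax = 0.0
                for k in range(p - 1):
                    kk = k + 1 if k >= j else k
                    r = S[kk, j]
                    for l in range(p - 1):
                        if l == k:
                            continue
                        ll = l + 1 if l >= j else l
                        r -= W[kk, ll] * B[l, j]
                    if r > lam:
                        bnew = (r - lam) / W[kk, kk]
                    elif r < -lam:
                        bnew = (r + lam) / W[kk, kk]
                    else:
                        bnew = 0.0
                    d = abs(bnew - B[k, j])
                    if d > dmax:
                        dmax = d
                    B[k, j] = bnew
                if dmax < tol:
                    break
            for k in range(p - 1):
                kk = k + 1 if k >= j else k
                v = 0.0
                for l in range(p - 1):
                    ll = l + 1 if l >= j else l
                    v += W[kk, ll] * B[l, j]
                d = abs(v - W[kk, j])
                if d > max_delta:
                    max_delta = d
                W[kk, j] = v
                W[j, kk] = v
        n_sweeps = sweep + 1
        if max_delta < tol:
            converged = True
            break
    return n_sweeps, converged, max_delta


def partials_from_precision(K: np.ndarray, zero_tol: float = ZERO_TOL) -> np.ndarray:
    """Partial correlations −κ_ij/√(κ_ii κ_jj), dust below ``zero_tol`` zeroed."""
    d = np.sqrt(np.diag(K))
    w = -K / np.outer(d, d)
    np.fill_diagonal(w, 0.0)
    w[np.abs(w) < zero_tol] = 0.0
    return 0.5 * (w + w.T)


def ebic(loglik: float, edge_count: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC: −2l + E·log n + 4·E·γ·log p."""
    return -2.0 * loglik + edge_count * np.log(n) + 4.0 * edge_count * gamma * np.log(p)


def _as_matrix(S: AssociationMatrix | np.ndarray) -> np.ndarray:
    if isinstance(S, AssociationMatrix):
        return S.values
    return np.asarray(S, dtype=float)


def _solve_one(
    S: np.ndarray,
    lam: float,
    config: GlassoConfig,
    W: np.ndarray,
    B: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Run the CD solver in place on warm-start state (W, B); return (K, sweeps)."""
    if lam == 0.0:
        # unpenalized MLE: K = S^{-1} (requires well-conditioned S)
        K = np.linalg.inv(S)
        W[:] = S
        return 0.5 * (K + K.T), 0
    n_sweeps, converged, max_delta = _glasso_cd(
        S, lam, W, B, config.convergence_tol, config.max_iter, 200
    )
    if not converged:
        raise ConvergenceError("glasso did not converge", n_sweeps, max_delta)
    Wsym = 0.5 * (W + W.T)
    K = np.linalg.inv(Wsym)
    return 0.5 * (K + K.T), n_sweeps


def _init_state(S: np.ndarray, config: GlassoConfig, lam: float) -> tuple[np.ndarray, np.ndarray]:
    W = S.copy()
    if config.penalize_diagonal:
        W[np.diag_indices_from(W)] += lam
    p = S.shape[0]
    return W, np.zeros((p - 1, p))


def _fit_stats(
    S: np.ndarray, K: np.ndarray, n: int, gamma: float
) -> tuple[np.ndarray, float, int, float]:
    w = partials_from_precision(K)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ConvergenceError("estimated precision matrix is not PD", 0, np.inf)
    loglik = 0.5 * n * (logdet - float(np.sum(S * K)))
    E = int(np.count_nonzero(np.triu(w, 1)))
    return w, loglik, E, ebic(loglik, E, n, S.shape[0], gamma)


def glasso_fit(
    S: AssociationMatrix | np.ndarray,
    lam: float,
    config: GlassoConfig | None = None,
    n: int | None = None,
) -> GGMFit:
    """Graphical lasso at a single penalty λ ≥ 0."""
    config = config or GlassoConfig()
    Sv = _as_matrix(S)
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    if np.linalg.eigvalsh(Sv)[0] <= 0 and lam == 0.0:
        raise ValidationError("S must be positive definite for an unpenalized fit")
    if n is None:
        n = S.n_effective if isinstance(S, AssociationMatrix) else Sv.shape[0] + 1
    W, B = _init_state(Sv, config, lam)
    K, n_sweeps = _solve_one(Sv, lam, config, W, B)
    w, loglik, E, crit = _fit_stats(Sv, K, n, config.gamma)
    method = S.method if isinstance(S, AssociationMatrix) else "matrix"
    nodes = [f"V{j + 1}" for j in range(Sv.shape[0])]
    net = Network(
        nodes,
        w,
        {"estimator": "glasso", "method": method, "lambda": float(lam),
         "gamma": config.gamma, "n": int(n)},
    )
    return GGMFit(K, net, float(lam), loglik, E, crit, int(n), n_sweeps)


def lambda_path(S: AssociationMatrix | np.ndarray, config: GlassoConfig | None = None) -> np.ndarray:
    """Descending log-spaced penalties from λ_max = max off-diagonal |S|."""
    config = config or GlassoConfig()
    Sv = _as_matrix(S)
    off = np.abs(Sv - np.diag(np.diag(Sv)))
    lam_max = float(off.max())
    if lam_max == 0.0:
        warnings.warn("all off-diagonal correlations are zero; path collapses to {0}",
                      stacklevel=2)
        return np.array([0.0])
    if config.n_lambdas == 1:
        return np.array([lam_max])
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambdas)


def _fast_select(
    Sv: np.ndarray, n: int, config: GlassoConfig
) -> tuple[np.ndarray, np.ndarray, float, float, int, float, np.ndarray]:
    """EBIC-minimizing glasso over the λ path; warm starts, exhaustive scan.

    Returns (weights, K, lambda, loglik, edge_count, ebic, path_records).
    The hot loops (bootstrap, permutation test) call this directly.
    """
    lambdas = lambda_path(Sv, config)
    W, B = _init_state(Sv, config, lambdas[0])
    best = None
    records = np.empty((lambdas.size, 4))
    for i, lam in enumerate(lambdas):
        if config.penalize_diagonal:
            W[np.diag_indices_from(W)] = np.diag(Sv) + lam
        K, _ = _solve_one(Sv, lam, config, W, B)
        w, loglik, E, crit = _fit_stats(Sv, K, n, config.gamma)
        records[i] = (lam, loglik, E, crit)
        if best is None or crit < best[5]:
            best = (w, K, float(lam), loglik, E, crit)
    w, K, lam, loglik, E, crit = best
    return w, K, lam, loglik, E, crit, records


def select_network(
    data_or_S: SymptomDataset | AssociationMatrix | np.ndarray,
    config: GlassoConfig | None = None,
    n: int | None = None,
    method: str = "pearson",
) -> GGMFit:
    """Fit the whole λ path and return the EBIC-minimizing network.

    Accepts a dataset (correlations computed via ``method``) or a
    ready-made association matrix with known sample size ``n``.
    """
    config = config or GlassoConfig()
    if isinstance(data_or_S, SymptomDataset):
        S = correlation_matrix(data_or_S, method=method)
        nodes = data_or_S.item_names
        n = data_or_S.n
    else:
        S = data_or_S
        nodes = None
        if n is None:
            if isinstance(S, AssociationMatrix):
                n = S.n_effective
            else:
                raise ValidationError("sample size n is required for EBIC selection")
    Sv = _as_matrix(S)
    if nodes is None:
        nodes = [f"V{j + 1}" for j in range(Sv.shape[0])]
    w, K, lam, loglik, E, crit, records = _fast_select(Sv, int(n), config)
    corr_method = S.method if isinstance(S, AssociationMatrix) else method
    net = Network(
        list(nodes),
        w,
        {"estimator": "ebic-glasso", "method": corr_method, "lambda": lam,
         "gamma": config.gamma, "n": int(n)},
    )
    return GGMFit(K, net, lam, loglik, E, crit, int(n), path=records)


def global_strength(net: Network | np.ndarray) -> float:
    """Sum of absolute edge weights over the upper triangle."""
    w = net.weights if isinstance(net, Network) else np.asarray(net)
    return float(np.abs(np.triu(w, 1)).sum())
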