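"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route disjoint from the package
implementation: direct numerical maximization of the penalized
likelihood (vs coordinate-descent glasso), exhaustive simple-path
enumeration (vs Dijkstra/Brandes), and 2-D numerical quadrature of the
bivariate normal (vs the closed-form CDF used by the polychoric
estimator).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate, optimize


def brute_force_glasso(S: np.ndarray, lam: float, n_restarts: int = 4) -> np.ndarray:
    """Maximize log det K − tr(SK) − λΣ_{i≠j}|κ_ij| by Nelder–Mead on a
    Cholesky parametrization, with random restarts and a polish pass."""
    p = S.shape[0]
    tri = np.tril_indices(p)

    def unpack(theta):
        L = np.zeros((p, p))
        L[tri] = theta
        for i in range(p):
            L[i, i] = np.exp(L[i, i])
        return L @ L.T

    def neg(theta):
        K = unpack(theta)
        _, logdet = np.linalg.slogdet(K)
        pen = lam * (np.abs(K).sum() - np.trace(np.abs(K)))
        return -(logdet - np.sum(S * K) - pen)

    opts = {"xatol": 1e-13, "fatol": 1e-15, "maxiter": 200_000, "maxfev": 200_000}
    best = None
    for trial in range(n_restarts):
        rng = np.random.default_rng(trial)
        theta0 = np.zeros(len(tri[0])) if trial == 0 else rng.normal(0.0, 0.3, len(tri[0]))
        res = optimize.minimize(neg, theta0, method="Nelder-Mead", options=opts)
        res = optimize.minimize(neg, res.x, method="Nelder-Mead", options=opts)
        if best is None or res.fun < best.fun:
            best = res
    return unpack(best.x)


def enumerate_path_centralities(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closeness (1/Σ distances, 0 when any partner unreachable) and
    betweenness (fractional, unordered pairs) by exhaustive enumeration
    of simple paths with edge lengths 1/|w|.  Feasible for p ≤ 8."""
    p = weights.shape[0]
    with np.errstate(divide="ignore"):
        length = np.where(weights != 0.0, 1.0 / np.abs(weights), np.inf)

    def all_simple_paths(s, t):
        others = [v for v in range(p) if v not in (s, t)]
        for k in range(len(others) + 1):
            for mid in itertools.permutations(others, k):
                path = (s, *mid, t)
                cost = sum(length[a, b] for a, b in zip(path, path[1:]))
                if np.isfinite(cost):
                    yield path, cost

    shortest = np.full((p, p), np.inf)
    np.fill_diagonal(shortest, 0.0)
    sp_paths: dict[tuple[int, int], list[tuple]] = {}
    for s in range(p):
        for t in range(s + 1, p):
            best, paths = np.inf, []
            for path, cost in all_simple_paths(s, t):
                if cost < best - 1e-12:
                    best, paths = cost, [path]
                elif abs(cost - best) <= 1e-12:
                    paths.append(path)
            shortest[s, t] = shortest[t, s] = best
            sp_paths[(s, t)] = paths

    closeness = np.zeros(p)
    for i in range(p):
        d = [shortest[i, j] for j in range(p) if j != i]
        if all(np.isfinite(x) for x in d):
            total = sum(d)
            closeness[i] = 1.0 / total if total > 0 else 0.0

    betweenness = np.zeros(p)
    for (s, t), paths in sp_paths.items():
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                betweenness[v] += 1.0 / len(paths)
    return closeness, betweenness


def bvn_cdf_quad(a: float, b: float, rho: float) -> float:
    """P(X ≤ a, Y ≤ b) for standard bivariate normal via 2-D quadrature."""
    det = 1.0 - rho * rho
    norm = 1.0 / (2.0 * np.pi * np.sqrt(det))

    def density(y, x):
        return norm * np.exp(-(x * x - 2.0 * rho * x * y + y * y) / (2.0 * det))

    val, _ = integrate.dblquad(density, -8.0, a, -8.0, b, epsabs=1e-10)
    return val


def tetrachoric_quad(table: np.ndarray, tau_x: float, tau_y: float) -> float:
    """Tetrachoric MLE for a 2×2 table with fixed thresholds, using
    quadrature cell probabilities and bounded scalar search."""
    from scipy.stats import norm

    px, py = norm.cdf(tau_x), norm.cdf(tau_y)

    def negloglik(rho):
        p00 = bvn_cdf_quad(tau_x, tau_y, rho)
        probs = np.array(
            [[p00, px - p00], [py - p00, 1.0 - px - py + p00]]
        )
        probs = np.clip(probs, 1e-12, 1.0)
        return -float(np.sum(table * np.log(probs)))

    res = optimize.minimize_scalar(
        negloglik, bounds=(-0.99, 0.99), method="bounded", options={"xatol": 1e-6}
    )
    return float(res.x)
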