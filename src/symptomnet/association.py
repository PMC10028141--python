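"""Correlation matrices feeding the graphical lasso.

Pearson (default), Spearman, and two-step polychoric/tetrachoric
estimators over ordinal item scores, with eigenvalue-clipping repair to
guarantee a positive-definite input for the penalized likelihood.

The polychoric estimator is the standard two-step procedure: item
thresholds are fixed at inverse-normal cumulative marginal proportions,
then the single latent correlation is found by bounded scalar
maximization of the bivariate-normal cell likelihood.  A binary×binary
pair reduces to the tetrachoric case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datasets import SymptomDataset, ValidationError

__all__ = [
    "AssociationMatrix",
    "correlation_matrix",
    "polychoric_pair",
    "nearest_pd_repair",
]

_EIG_FLOOR = 1e-8
_RHO_BOUND = 0.999


@dataclass
class AssociationMatrix:
    """Symmetric correlation matrix with unit diagonal, ready for glasso."""

    values: np.ndarray
    method: str
    n_effective: int
    smoothed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("association matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("association matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValidationError("association matrix diagonal must be 1")
        if np.any(np.abs(v) > 1.0 + 1e-10):
            raise ValidationError("correlations must lie in [-1, 1]")
        self.values = 0.5 * (v + v.T)

    @property
    def p(self) -> int:
        return self.values.shape[0]


def nearest_pd_repair(
    m: np.ndarray, floor: float = _EIG_FLOOR
) -> tuple[np.ndarray, bool]:
    """Eigenvalue clipping at ``floor`` plus re-standardization to unit diagonal.

    Returns ``(repaired, was_repaired)``; a no-op (flag ``False``) when the
    input is already positive definite at the floor.  Repeated clipping
    makes the operation idempotent.
    """
    m = np.asarray(m, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValidationError("nearest_pd_repair expects a symmetric matrix")
    out = 0.5 * (m + m.T)
    repaired = False
    for _ in range(100):
        vals = np.linalg.eigvalsh(out)
        if vals[0] >= floor:
            break
        repaired = True
        vals_c, vecs = np.linalg.eigh(out)
        out = (vecs * np.maximum(vals_c, floor)) @ vecs.T
        d = 1.0 / np.sqrt(np.diag(out))
        out = out * np.outer(d, d)
        out = 0.5 * (out + out.T)
        np.fill_diagonal(out, 1.0)
    return (out if repaired else m.copy()), repaired


def _column_checks(X: np.ndarray, names: list[str]) -> None:
    variances = X.var(axis=0)
    for j, v in enumerate(variances):
        if v == 0.0:
            raise ValidationError(
                f"item {names[j]!r} has zero variance; correlation undefined"
            )


def _corr_values(X: np.ndarray, method: str, names: list[str]) -> np.ndarray:
    _column_checks(X, names)
    p = X.shape[1]
    if method == "pearson":
        r = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        res = stats.spearmanr(X)
        r = np.atleast_2d(res.statistic)
        if r.shape != (p, p):  # p == 2 returns a scalar
            val = float(res.statistic)
            r = np.array([[1.0, val], [val, 1.0]])
    elif method == "polychoric":
        r = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                r[i, j] = r[j, i] = polychoric_pair(X[:, i], X[:, j])
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def correlation_matrix(data: SymptomDataset, method: str = "pearson") -> AssociationMatrix:
    """Item correlation matrix by the chosen method, PD-repaired if needed."""
    X = np.asarray(data.scores, dtype=float)
    if data.n < data.p + 1:
        warnings.warn(
            f"n={data.n} below the recommended floor p+1={data.p + 1}; "
            "correlations may be rank deficient",
            stacklevel=2,
        )
    r = _corr_values(X, method, data.item_names)
    repaired_vals, smoothed = nearest_pd_repair(r)
    return AssociationMatrix(
        values=repaired_vals if smoothed else r,
        method=method,
        n_effective=data.n,
        smoothed=smoothed,
    )


# ---------------------------------------------------------------------------
# polychoric / tetrachoric
# ---------------------------------------------------------------------------

def _thresholds(col: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Inverse-normal thresholds from cumulative marginal proportions."""
    counts = np.array([(col == lv).sum() for lv in levels], dtype=float)
    cum = np.cumsum(counts)[:-1] / col.size
    return stats.norm.ppf(cum)


def _cell_probabilities(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate-normal rectangle probabilities for all threshold cells."""
    ax = np.concatenate([[-np.inf], tau_x, [np.inf]])
    ay = np.concatenate([[-np.inf], tau_y, [np.inf]])
    nx, ny = ax.size, ay.size
    # CDF at every finite grid corner in one vectorized call
    cdf = np.zeros((nx, ny))
    cdf[-1, -1] = 1.0
    cdf[:-1, -1] = stats.norm.cdf(ax[:-1])
    cdf[-1, :-1] = stats.norm.cdf(ay[:-1])
    fin_x, fin_y = np.isfinite(ax), np.isfinite(ay)
    pts = np.array(
        [(ax[i], ay[j]) for i in range(nx) for j in range(ny) if fin_x[i] and fin_y[j]]
    )
    if pts.size:
        vals = stats.multivariate_normal.cdf(
            pts, mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        vals = np.atleast_1d(vals)
        k = 0
        for i in range(nx):
            for j in range(ny):
                if fin_x[i] and fin_y[j]:
                    cdf[i, j] = vals[k]
                    k += 1
    # -inf rows/columns contribute zero mass
    cdf[np.where(ax == -np.inf)[0], :] = 0.0
    cdf[:, np.where(ay == -np.inf)[0]] = 0.0
    probs = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.clip(probs, 1e-300, 1.0)


def polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step polychoric correlation between two ordinal columns.

    Raises :class:`ValidationError` unless both columns show at least two
    levels.  A degenerate table whose likelihood increases without bound
    is clamped at ±0.999 with a warning.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("polychoric_pair expects two equal-length 1-D columns")
    lx, ly = np.unique(x), np.unique(y)
    if lx.size < 2 or ly.size < 2:
        raise ValidationError("each column needs at least 2 observed levels")
    tau_x = _thresholds(x, lx)
    tau_y = _thresholds(y, ly)
    table = np.zeros((lx.size, ly.size))
    for i, lvx in enumerate(lx):
        for j, lvy in enumerate(ly):
            table[i, j] = np.sum((x == lvx) & (y == lvy))

    def negloglik(rho: float) -> float:
        probs = _cell_probabilities(tau_x, tau_y, rho)
        return -float(np.sum(table * np.log(probs)))

    res = optimize.minimize_scalar(
        negloglik,
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    if _RHO_BOUND - abs(rho) < 1e-4:
        rho = float(np.sign(rho)) * _RHO_BOUND
        warnings.warn(
            "polychoric likelihood unbounded for this table; estimate clamped at "
            f"{rho:+.3f}",
            stacklevel=2,
        )
    return rho
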