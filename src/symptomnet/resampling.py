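"""Bootstrap accuracy and stability for estimated networks.

Three procedures, all re-running the full estimation pipeline
(correlation → EBIC-glasso) per replicate:

* **non-parametric edge bootstrap** — case resampling with replacement
  at full n; per-edge percentile confidence intervals;
* **bootstrapped difference tests** — an edge pair (or node pair, per
  centrality index) differs significantly when the percentile interval
  of the per-replicate difference excludes zero (no multiplicity
  correction, matching common practice — treat as descriptive);
* **case-dropping bootstrap** — subsamples without replacement at
  increasing drop proportions; the correlation-stability coefficient
  CS-C is the largest drop proportion at which at least
  ``stability_probability`` of subsamples correlate ≥
  ``stability_correlation`` with the full-sample centrality vector
  (0 if none).

Replicate RNG streams are spawned from the master seed, so results are
bit-reproducible and independent of execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .association import _corr_values, nearest_pd_repair
from .centrality import INDICES, centrality_table
from .datasets import Network, SymptomDataset, ValidationError
from .ggm import ConvergenceError, GlassoConfig, _fast_select

__all__ = [
    "BootstrapConfig",
    "BootstrapSummary",
    "StabilityResult",
    "bootstrap_edges",
    "edge_difference_test",
    "centrality_difference_test",
    "case_dropping_stability",
]

#: estimator signature: raw integer score matrix -> weight matrix
WeightEstimator = Callable[[np.ndarray], np.ndarray]


def default_estimator(
    item_names: Sequence[str],
    method: str = "pearson",
    config: GlassoConfig | None = None,
) -> WeightEstimator:
    """The standard pipeline: correlations by ``method``, then EBIC-glasso."""
    config = config or GlassoConfig()
    names = list(item_names)

    def estimate(X: np.ndarray) -> np.ndarray:
        r = _corr_values(np.asarray(X, dtype=float), method, names)
        r, _ = nearest_pd_repair(r)
        w, *_ = _fast_select(r, X.shape[0], config)
        return w

    return estimate


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate counts, CI level, seed, and the case-dropping grid."""

    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    drop_proportions: tuple[float, ...] = tuple(np.linspace(0.05, 0.75, 10).round(10))
    stability_correlation: float = 0.7
    stability_probability: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must lie in (0, 1)")
        d = self.drop_proportions
        if any(not 0.0 < x < 1.0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValidationError("drop proportions must be strictly increasing in (0, 1)")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")


@dataclass
class BootstrapSummary:
    """Edge bootstrap output: point estimates, draws, percentile CIs."""

    nodes: list[str]
    point: np.ndarray
    draws: np.ndarray  # (n_kept, p, p)
    mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    ci_level: float
    n_failed: int
    centrality_draws: Mapping[str, np.ndarray] = field(default_factory=dict)
    centrality_point: Mapping[str, np.ndarray] = field(default_factory=dict)

    def edge_index(self, a: str, b: str) -> tuple[int, int]:
        i, j = self.nodes.index(a), self.nodes.index(b)
        return (i, j) if i < j else (j, i)


def _spawn_rngs(seed: int, count: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(count)]


def bootstrap_edges(
    data: SymptomDataset,
    config: BootstrapConfig | None = None,
    method: str = "pearson",
    glasso_config: GlassoConfig | None = None,
    estimator: WeightEstimator | None = None,
    centrality_indices: Sequence[str] = (),
) -> BootstrapSummary:
    """Non-parametric case bootstrap of every edge weight (and, optionally,
    of node centralities for the difference tests)."""
    config = config or BootstrapConfig()
    if data.n < 100:
        warnings.warn(f"n={data.n} is small for a case bootstrap", stacklevel=2)
    estimate = estimator or default_estimator(data.item_names, method, glasso_config)
    point = estimate(data.scores)
    cent_point = _centralities(point, data.item_names, centrality_indices)

    draws, cent_draws, n_failed = [], [], 0
    for rng in _spawn_rngs(config.seed, config.n_boot):
        idx = rng.integers(0, data.n, size=data.n)
        try:
            w = estimate(data.scores[idx])
        except (ConvergenceError, ValidationError):
            n_failed += 1
            continue
        draws.append(w)
        cent_draws.append(_centralities(w, data.item_names, centrality_indices))
    if n_failed > 0.05 * config.n_boot:
        raise RuntimeError(
            f"{n_failed}/{config.n_boot} bootstrap replicates failed estimation"
        )
    arr = np.stack(draws)
    alpha = 1.0 - config.ci_level
    lo, hi = np.quantile(arr, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    centrality_draws = {
        idx_name: np.stack([c[idx_name] for c in cent_draws])
        for idx_name in centrality_indices
    }
    return BootstrapSummary(
        nodes=list(data.item_names),
        point=point,
        draws=arr,
        mean=arr.mean(axis=0),
        ci_lower=lo,
        ci_upper=hi,
        ci_level=config.ci_level,
        n_failed=n_failed,
        centrality_draws=centrality_draws,
        centrality_point=cent_point,
    )


def _centralities(
    w: np.ndarray, nodes: Sequence[str], indices: Sequence[str]
) -> dict[str, np.ndarray]:
    if not indices:
        return {}
    bad = set(indices) - set(INDICES)
    if bad:
        raise ValueError(f"unknown centrality index: {sorted(bad)}")
    table = centrality_table(Network(list(nodes), w))
    return {name: table[name].to_numpy() for name in indices}


def _interval_excludes_zero(diffs: np.ndarray, level: float) -> bool:
    alpha = 1.0 - level
    lo, hi = np.quantile(diffs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return bool(lo > 0.0 or hi < 0.0)


def edge_difference_test(
    summary: BootstrapSummary, edge_a: tuple[str, str], edge_b: tuple[str, str]
) -> bool:
    """True when the percentile interval of w_a − w_b over replicates excludes 0."""
    ia = summary.edge_index(*edge_a)
    ib = summary.edge_index(*edge_b)
    if ia == ib:
        raise ValidationError(f"self-comparison of edge {edge_a}")
    diffs = summary.draws[:, ia[0], ia[1]] - summary.draws[:, ib[0], ib[1]]
    return _interval_excludes_zero(diffs, summary.ci_level)


def centrality_difference_test(
    summary: BootstrapSummary, index: str, node_a: str, node_b: str
) -> bool:
    """Bootstrapped difference test between two nodes' centrality values."""
    if index not in summary.centrality_draws:
        raise ValidationError(
            f"index {index!r} was not tracked; pass centrality_indices to bootstrap_edges"
        )
    if node_a == node_b:
        raise ValidationError(f"self-comparison of node {node_a!r}")
    ia, ib = summary.nodes.index(node_a), summary.nodes.index(node_b)
    diffs = summary.centrality_draws[index][:, ia] - summary.centrality_draws[index][:, ib]
    return _interval_excludes_zero(diffs, summary.ci_level)


@dataclass
class StabilityResult:
    """Case-dropping curve and the correlation-stability coefficient."""

    index: str
    curve: pd.DataFrame  # proportion, mean_correlation, fraction_above, n_valid
    cs: float
    correlations: Mapping[float, np.ndarray]


def case_dropping_stability(
    data: SymptomDataset,
    index: str = "strength",
    config: BootstrapConfig | None = None,
    method: str = "pearson",
    glasso_config: GlassoConfig | None = None,
    estimator: WeightEstimator | None = None,
) -> StabilityResult:
    """Case-dropping bootstrap of one centrality index with CS-C.

    For each drop proportion d the estimator is re-run on ``n_boot``
    subsamples of size round((1−d)·n) drawn without replacement, and the
    Pearson correlation across nodes between the subsample and
    full-sample centrality vectors is recorded.  Proportions leaving
    fewer than p+1 cases are skipped with a warning.
    """
    if index not in INDICES:
        raise ValueError(f"index must be one of {INDICES}, got {index!r}")
    config = config or BootstrapConfig()
    estimate = estimator or default_estimator(data.item_names, method, glasso_config)
    full = _centralities(estimate(data.scores), data.item_names, (index,))[index]

    rows, correlations = [], {}
    rngs = iter(_spawn_rngs(config.seed, config.n_boot * len(config.drop_proportions)))
    for d in config.drop_proportions:
        m = int(round((1.0 - d) * data.n))
        if m < data.p + 1:
            warnings.warn(
                f"drop proportion {d:.2f} leaves {m} < p+1 cases; skipped", stacklevel=2
            )
            for _ in range(config.n_boot):
                next(rngs)
            continue
        cors = []
        for _ in range(config.n_boot):
            rng = next(rngs)
            idx = rng.choice(data.n, size=m, replace=False)
            try:
                sub = _centralities(estimate(data.scores[idx]), data.item_names, (index,))[index]
            except (ConvergenceError, ValidationError):
                continue
            if np.std(sub) == 0.0 or np.std(full) == 0.0:
                continue  # correlation undefined; replicate dropped
            cors.append(float(np.corrcoef(full, sub)[0, 1]))
        cors = np.asarray(cors)
        correlations[float(d)] = cors
        frac = float(np.mean(cors >= config.stability_correlation)) if cors.size else np.nan
        rows.append(
            {
                "proportion": float(d),
                "mean_correlation": float(cors.mean()) if cors.size else np.nan,
                "fraction_above": frac,
                "n_valid": int(cors.size),
            }
        )
    curve = pd.DataFrame(rows)
    cs = 0.0
    for row in rows:
        if row["n_valid"] and row["fraction_above"] >= config.stability_probability:
            cs = max(cs, row["proportion"])
    return StabilityResult(index=index, curve=curve, cs=cs, correlations=correlations)
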