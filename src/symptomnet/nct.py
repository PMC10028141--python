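"""Permutation-based Network Comparison Test (NCT) between two groups.

Two networks are estimated with identical settings, one per group, and
compared on:

* **network structure** — M = max_{i<j} |w_ij^A − w_ij^B|;
* **global strength** — S = | Σ|w^A| − Σ|w^B| | (difference of summed
  absolute edge weights);
* **individual edges** — per-edge |differences| with Holm–Bonferroni
  step-down adjustment.

The reference distribution pools all rows, randomly re-splits them into
the original group sizes, and re-estimates both networks each
iteration.  P-values use add-one smoothing,
p = (1 + #{permuted ≥ observed}) / (1 + iterations), so they are never
exactly zero.  Because permutations act on the pooled rows, swapping
the group labels leaves the structure and strength p-values unchanged
under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .association import _corr_values, nearest_pd_repair
from .datasets import SymptomDataset, ValidationError
from .ggm import GlassoConfig, _fast_select, global_strength

__all__ = ["NCTConfig", "NCTResult", "nct_run", "holm_adjust"]


@dataclass(frozen=True)
class NCTConfig:
    """Permutation count, seed, and per-edge test selection."""

    iterations: int = 1000
    seed: int = 0
    test_edges: bool = True
    #: "all" tests every upper-triangle pair; "observed" restricts to edges
    #: nonzero in at least one of the two observed networks
    edge_selection: str = "all"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.edge_selection not in ("all", "observed"):
            raise ValidationError("edge_selection must be 'all' or 'observed'")


@dataclass
class NCTResult:
    """Observed statistics, permutation p-values, per-edge Holm-adjusted p-values."""

    m_observed: float
    s_observed: float
    p_structure: float
    p_strength: float
    edges: list[tuple[str, str]]
    edge_diffs: np.ndarray
    edge_p: np.ndarray
    edge_p_holm: np.ndarray
    iterations: int
    seed: int
    weights_a: np.ndarray
    weights_b: np.ndarray
    nodes: list[str] = field(default_factory=list)

    def significant_edges(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return [e for e, p in zip(self.edges, self.edge_p_holm) if p < alpha]


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values, in the input order.

    adjusted(k) = max_{j ≤ k} min(1, (m − j + 1) · p_(j)) over the
    ascending ordering.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValidationError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    stepped = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(stepped)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _statistics(
    wa: np.ndarray, wb: np.ndarray, iu: tuple[np.ndarray, np.ndarray]
) -> tuple[float, float, np.ndarray]:
    diffs = np.abs(wa[iu] - wb[iu])
    m_stat = float(diffs.max())
    s_stat = abs(global_strength(wa) - global_strength(wb))
    return m_stat, s_stat, diffs


def nct_run(
    data_a: SymptomDataset,
    data_b: SymptomDataset,
    config: NCTConfig | None = None,
    method: str = "pearson",
    glasso_config: GlassoConfig | None = None,
) -> NCTResult:
    """Permutation NCT between two disjoint groups sharing one item battery."""
    config = config or NCTConfig()
    glasso_config = glasso_config or GlassoConfig()
    if data_a.item_names != data_b.item_names:
        raise ValidationError("both datasets must share the same items")
    if set(data_a.group.tolist()) & set(data_b.group.tolist()):
        raise ValidationError("group label sets must be disjoint")
    names = data_a.item_names
    p = len(names)
    iu = np.triu_indices(p, 1)

    def estimate(X: np.ndarray) -> np.ndarray:
        r = _corr_values(np.asarray(X, dtype=float), method, names)
        r, _ = nearest_pd_repair(r)
        w, *_ = _fast_select(r, X.shape[0], glasso_config)
        return w

    wa = estimate(data_a.scores)
    wb = estimate(data_b.scores)
    m_obs, s_obs, diffs_all = _statistics(wa, wb, iu)

    if config.edge_selection == "observed":
        keep = (wa[iu] != 0.0) | (wb[iu] != 0.0)
    else:
        keep = np.ones(iu[0].size, dtype=bool)
    edge_idx = np.where(keep)[0]
    edges = [(names[iu[0][k]], names[iu[1][k]]) for k in edge_idx]
    obs_edge_diffs = diffs_all[edge_idx]

    # canonical pooled order (sorted by group-label key): all permutation
    # statistics are symmetric in the two groups, so swapping the
    # arguments yields the identical permutation set and p-values
    key_a = tuple(sorted(set(data_a.group.tolist())))
    key_b = tuple(sorted(set(data_b.group.tolist())))
    first, second = (data_a, data_b) if key_a <= key_b else (data_b, data_a)
    pooled = np.vstack([first.scores, second.scores])
    n_a, n_total = first.n, pooled.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    m_count = s_count = 0
    edge_counts = np.zeros(edge_idx.size)
    for _ in range(config.iterations):
        for attempt in range(2):
            perm = rng.permutation(n_total)
            try:
                pa = estimate(pooled[perm[:n_a]])
                pb = estimate(pooled[perm[n_a:]])
                break
            except Exception:
                if attempt == 1:
                    raise
        m_perm, s_perm, d_perm = _statistics(pa, pb, iu)
        m_count += m_perm >= m_obs
        s_count += s_perm >= s_obs
        if config.test_edges and edge_idx.size:
            edge_counts += d_perm[edge_idx] >= obs_edge_diffs

    denom = 1.0 + config.iterations
    p_structure = (1.0 + m_count) / denom
    p_strength = (1.0 + s_count) / denom
    if config.test_edges and edge_idx.size:
        edge_p = (1.0 + edge_counts) / denom
        edge_p_holm = holm_adjust(edge_p)
    else:
        edges, obs_edge_diffs = [], np.empty(0)
        edge_p = edge_p_holm = np.empty(0)
    return NCTResult(
        m_observed=m_obs,
        s_observed=s_obs,
        p_structure=p_structure,
        p_strength=p_strength,
        edges=edges,
        edge_diffs=obs_edge_diffs,
        edge_p=edge_p,
        edge_p_holm=edge_p_holm,
        iterations=config.iterations,
        seed=config.seed,
        weights_a=wa,
        weights_b=wb,
        nodes=list(names),
    )
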