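"""Synthetic three-group symptom data with known partial-correlation structure.

The generator mirrors the data-generating assumptions of a Gaussian
graphical model analysis of ordinal questionnaire items: each group has
a latent multivariate-normal vector with unit variances and a sparse
true partial-correlation network organised into depression, anxiety and
PTSD communities; observed item scores are the latent values cut at
fixed thresholds (three cut-points for 0–3 items, one for yes/no
items).

Group differences are injected as edge overrides on the shared base
network: by default the sexual-abuse group strengthens PTSD–PTSD edges,
the emotional-abuse group strengthens suicide-item edges, and the
physical-abuse group strengthens anxiety edges, with group sizes
1,191 / 1,272 / 3,479.

Randomness: every sampling call uses ``numpy.random.Generator`` (PCG64)
seeded from the spec's integer seed; the three-group builder derives
one sub-stream per group by a fixed integer offset from the master
seed, so groups are decoupled and every run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datasets import (
    SymptomDataset,
    ValidationError,
    concat_datasets,
    items_for_nodes,
)

__all__ = [
    "ConstructionError",
    "TrueNetworkSpec",
    "GroupSimSpec",
    "make_true_network",
    "perturb_network",
    "sample_group",
    "make_three_group_study",
    "default_thresholds",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_PERTURBATIONS",
]


class ConstructionError(RuntimeError):
    """A requested true network cannot be made positive definite."""


BLOCK_NAMES = ("depression", "anxiety", "ptsd")

#: group sizes of the emulated childhood-trauma cohort (EA, PA, SA)
DEFAULT_GROUP_SIZES: tuple[int, int, int] = (1191, 1272, 3479)

#: default additive edge perturbations per group (partial-correlation scale)
DEFAULT_PERTURBATIONS: Mapping[str, Mapping[tuple[str, str], float]] = {
    "SA": {
        ("PTSD.7", "PTSD.9"): 0.25,
        ("PTSD.6", "PTSD.9"): 0.25,
        ("PTSD.3", "PTSD.4"): 0.25,
    },
    "EA": {
        ("PHQ.9", "PHQ.2"): 0.25,
        ("PHQ.9", "PHQ.8"): 0.25,
    },
    "PA": {
        ("GAD.4", "GAD.6"): 0.25,
        ("GAD.5", "PHQ.9"): 0.25,
    },
}

# per-group latent thresholds, calibrated once so simulated scale totals
# land near the cohort's reported group means (EA most severe);
# "ordinal" = 0-3 items, "binary" = yes/no items
GROUP_THRESHOLDS: Mapping[str, Mapping[str, tuple[float, ...]]] = {
    "EA": {"ordinal": (-0.70, 0.35, 1.20), "binary": (-0.28,)},
    "PA": {"ordinal": (-0.15, 0.75, 1.60), "binary": (0.14,)},
    "SA": {"ordinal": (-0.05, 0.85, 1.70), "binary": (0.17,)},
}
_FALLBACK_THRESHOLDS = {"ordinal": (-0.15, 0.75, 1.60), "binary": (0.14,)}

# fixed per-group seed offset (sub-stream discipline, see module docstring)
_GROUP_SEED_STRIDE = 100_003


@dataclass(frozen=True)
class TrueNetworkSpec:
    """Ground-truth sparse Gaussian graphical model over named symptom nodes."""

    nodes: tuple[str, ...]
    precision: np.ndarray
    blocks: tuple[str, ...]

    def __post_init__(self) -> None:
        K = np.asarray(self.precision, dtype=float)
        p = len(self.nodes)
        if K.shape != (p, p) or not np.allclose(K, K.T, atol=1e-10):
            raise ValidationError("precision must be a symmetric p × p matrix")
        if len(self.blocks) != p:
            raise ValidationError("one block label per node required")
        if np.linalg.eigvalsh(K)[0] <= 0:
            raise ConstructionError("implied precision matrix is not positive definite")
        if np.any(np.abs(self.partials_of(K)) >= 1.0):
            raise ValidationError("|partial correlation| must be < 1")

    @staticmethod
    def partials_of(K: np.ndarray) -> np.ndarray:
        d = np.sqrt(np.diag(K))
        P = -K / np.outer(d, d)
        np.fill_diagonal(P, 0.0)
        return P

    @property
    def p(self) -> int:
        return len(self.nodes)

    @property
    def partials(self) -> np.ndarray:
        """True partial-correlation matrix (zero diagonal)."""
        return self.partials_of(self.precision)

    @property
    def correlation(self) -> np.ndarray:
        """Marginal latent correlation matrix implied by the precision."""
        cov = np.linalg.inv(self.precision)
        d = 1.0 / np.sqrt(np.diag(cov))
        corr = cov * np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        return 0.5 * (corr + corr.T)

    def edge_set(self) -> set[tuple[str, str]]:
        P = self.partials
        out = set()
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if P[i, j] != 0.0:
                    out.add((self.nodes[i], self.nodes[j]))
        return out


def _block_nodes(p_dep: int, p_anx: int, p_ptsd: int) -> tuple[list[str], list[str]]:
    nodes = (
        [f"PHQ.{i}" for i in range(1, p_dep + 1)]
        + [f"GAD.{i}" for i in range(1, p_anx + 1)]
        + [f"PTSD.{i}" for i in range(1, p_ptsd + 1)]
    )
    blocks = (
        [BLOCK_NAMES[0]] * p_dep + [BLOCK_NAMES[1]] * p_anx + [BLOCK_NAMES[2]] * p_ptsd
    )
    return nodes, blocks


def make_true_network(
    p_dep: int = 9,
    p_anx: int = 7,
    p_ptsd: int = 10,
    within_weight: float = 0.25,
    bridge_weight: float = 0.12,
    density: float = 0.2,
    seed: int = 0,
    min_eigenvalue: float = 0.01,
) -> TrueNetworkSpec:
    """Block-structured sparse true network over three symptom communities.

    Within-block edges are sampled at the given density with weight
    ``within_weight``; a small fixed set of cross-block bridge edges gets
    ``bridge_weight``.  The implied precision matrix (unit diagonal,
    off-diagonal −w) is made positive definite by uniformly shrinking
    the off-diagonal block; shrinkage below a factor of 0.05 raises
    :class:`ConstructionError`.  Realised partial correlations are the
    nominal weights times the shrinkage factor.
    """
    for w in (within_weight, bridge_weight):
        if not -1.0 < w < 1.0:
            raise ValidationError("edge weights must lie in (-1, 1)")
    if not 0.0 < density <= 1.0:
        raise ValidationError("density must lie in (0, 1]")
    nodes, blocks = _block_nodes(p_dep, p_anx, p_ptsd)
    p = len(nodes)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    W = np.zeros((p, p))
    offsets = np.cumsum([0, p_dep, p_anx, p_ptsd])
    for b in range(3):
        lo, hi = offsets[b], offsets[b + 1]
        pairs = [(i, j) for i in range(lo, hi) for j in range(i + 1, hi)]
        k = int(round(density * len(pairs)))
        if pairs and k > 0:
            chosen = rng.choice(len(pairs), size=k, replace=False)
            for c in chosen:
                i, j = pairs[c]
                W[i, j] = W[j, i] = within_weight
    # fixed bridges: block b's last node to block b+1's first, plus one
    # depression-PTSD bridge
    bridges = []
    if p_dep and p_anx:
        bridges.append((offsets[1] - 1, offsets[1]))
    if p_anx and p_ptsd:
        bridges.append((offsets[2] - 1, offsets[2]))
    if p_dep and p_ptsd:
        bridges.append((0, p - 1))
    for i, j in bridges:
        W[i, j] = W[j, i] = bridge_weight

    factor = 1.0
    while factor >= 0.05:
        K = np.eye(p) - factor * W
        if np.linalg.eigvalsh(K)[0] >= min_eigenvalue:
            return TrueNetworkSpec(tuple(nodes), K, tuple(blocks))
        factor *= 0.95
    raise ConstructionError(
        "positive-definite repair failed: required shrinkage below the 0.05 bound"
    )


def perturb_network(
    base: TrueNetworkSpec, overrides: Mapping[tuple[str, str], float]
) -> TrueNetworkSpec:
    """Add ``delta`` to the true partial correlation of each named node pair.

    The perturbed network differs from ``base`` exactly on the
    overridden pairs.  The result must remain positive definite; no
    silent repair is applied (repair would touch every edge).
    """
    idx = {name: k for k, name in enumerate(base.nodes)}
    P = base.partials.copy()
    for (a, b), delta in overrides.items():
        if a not in idx or b not in idx:
            raise ValidationError(f"unknown node pair ({a!r}, {b!r})")
        if a == b:
            raise ValidationError(f"cannot override the diagonal cell ({a!r}, {a!r})")
        i, j = idx[a], idx[b]
        P[i, j] += delta
        P[j, i] = P[i, j]
    K = np.eye(base.p) - P
    if np.linalg.eigvalsh(K)[0] <= 0:
        raise ConstructionError("perturbed network lost positive definiteness")
    return TrueNetworkSpec(base.nodes, K, base.blocks)


def default_thresholds(
    nodes: Sequence[str], group: str
) -> dict[str, tuple[float, ...]]:
    """Per-item latent cut-points for a group (shared within instrument type)."""
    sev = GROUP_THRESHOLDS.get(group, _FALLBACK_THRESHOLDS)
    out = {}
    for name in nodes:
        kind = "binary" if name.startswith("PTSD") else "ordinal"
        out[name] = tuple(sev[kind])
    return out


@dataclass
class GroupSimSpec:
    """One group's simulation recipe: size, true network, thresholds, seed."""

    name: str
    size: int
    network: TrueNetworkSpec
    thresholds: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError("group size must be >= 1")
        if not self.thresholds:
            self.thresholds = default_thresholds(self.network.nodes, self.name)
        for name in self.network.nodes:
            if name not in self.thresholds:
                raise ValidationError(f"no thresholds for item {name!r}")
            cuts = tuple(self.thresholds[name])
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValidationError(f"cut-points for {name!r} must strictly increase")
            want = 1 if name.startswith("PTSD") else 3
            if len(cuts) != want:
                raise ValidationError(
                    f"item {name!r} needs {want} cut-point(s), got {len(cuts)}"
                )


def sample_group(spec: GroupSimSpec) -> SymptomDataset:
    """Draw one group's scores: latent MVN, then threshold to item levels.

    Latent vectors have unit variances and the spec network's
    partial-correlation structure; the observed level of item *j* is the
    number of its cut-points lying at or below the latent value.
    Identical seed ⇒ identical dataset.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    corr = spec.network.correlation
    L = np.linalg.cholesky(corr)
    Z = rng.standard_normal((spec.size, spec.network.p)) @ L.T
    scores = np.empty_like(Z, dtype=np.int64)
    for j, name in enumerate(spec.network.nodes):
        cuts = np.asarray(spec.thresholds[name], dtype=float)
        scores[:, j] = np.searchsorted(cuts, Z[:, j], side="right")
    items = items_for_nodes(spec.network.nodes)
    group = np.full(spec.size, spec.name, dtype=object)
    return SymptomDataset(items, scores, group)


def make_three_group_study(
    base: TrueNetworkSpec | None = None,
    perturbations: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
    sizes: Sequence[int] = DEFAULT_GROUP_SIZES,
    seed: int = 0,
    group_names: Sequence[str] = ("EA", "PA", "SA"),
) -> SymptomDataset:
    """Concatenated EA/PA/SA study: shared base network plus per-group overrides."""
    if len(sizes) != len(group_names):
        raise ValidationError("need one size per group")
    if base is None:
        base = make_true_network(seed=seed)
    if perturbations is None:
        perturbations = DEFAULT_PERTURBATIONS
    parts = []
    for k, (name, size) in enumerate(zip(group_names, sizes)):
        net = perturb_network(base, perturbations.get(name, {}))
        spec = GroupSimSpec(
            name=name,
            size=int(size),
            network=net,
            seed=seed + (k + 1) * _GROUP_SEED_STRIDE,
        )
        parts.append(sample_group(spec))
    return concat_datasets(parts)


def level_probabilities(cuts: Sequence[float]) -> np.ndarray:
    """Theoretical level frequencies implied by cut-points on a N(0,1) margin."""
    from scipy.stats import norm

    edges = np.concatenate([[-np.inf], np.asarray(cuts, float), [np.inf]])
    return np.diff(norm.cdf(edges))
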