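"""Domain types and file I/O for item-level symptom data and estimated networks.

The data model covers three self-report screening instruments commonly
combined in psychopathology network studies:

* **PHQ-9** — nine depression items scored 0 ("not at all") to 3
  ("nearly every day");
* **GAD-7** — seven anxiety items on the same 0–3 scale;
* **TSQ** — ten post-traumatic stress items with a yes/no (0/1) format,
  five intrusion and five hyperarousal symptoms.

Respondents carry a categorical group label (for childhood-trauma
subgroup analyses: emotional abuse ``EA``, physical abuse ``PA``, sexual
abuse ``SA``), and subgroup membership can be derived from CTQ-SF abuse
subscale scores via :func:`assign_ct_subgroup`.

Missing data policy: rows containing any missing item are dropped at
read time (listwise deletion) and the number of dropped rows is logged.
This keeps the sample size seen by every downstream estimator
unambiguous.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("symptomnet")

__all__ = [
    "SchemaError",
    "ValidationError",
    "ItemSpec",
    "SymptomDataset",
    "Network",
    "CTQScores",
    "default_items",
    "items_for_nodes",
    "read_dataset",
    "write_dataset",
    "read_network",
    "write_network",
    "assign_ct_subgroup",
    "CTQ_CUTOFFS",
]


class SchemaError(ValueError):
    """Input file does not match the declared column schema."""


class ValidationError(ValueError):
    """Data violate a domain invariant (range, shape, labels)."""


# instrument -> (min level, max level)
INSTRUMENT_LEVELS: Mapping[str, tuple[int, int]] = {
    "PHQ9": (0, 3),
    "GAD7": (0, 3),
    "TSQ": (0, 1),
}

# full-instrument item counts (enforced when a complete battery is expected)
INSTRUMENT_SIZES: Mapping[str, int] = {"PHQ9": 9, "GAD7": 7, "TSQ": 10}

# item-name prefix per instrument; "PTSD" is the conventional node prefix
# for the TSQ in symptom-network figures
INSTRUMENT_PREFIX: Mapping[str, str] = {"PHQ9": "PHQ", "GAD7": "GAD", "TSQ": "PTSD"}
PREFIX_INSTRUMENT: Mapping[str, str] = {v: k for k, v in INSTRUMENT_PREFIX.items()}

_PHQ9_LABELS = (
    "Anhedonia",
    "Sad mood",
    "Sleep problems",
    "Fatigue",
    "Appetite changes",
    "Guilt",
    "Concentration difficulty",
    "Motor",
    "Suicide",
)
_GAD7_LABELS = (
    "Nervousness",
    "Uncontrollable worry",
    "Excessive worry",
    "Trouble relaxing",
    "Restlessness",
    "Irritability",
    "Feeling afraid",
)
_TSQ_LABELS = (
    "Intrusive memories",
    "Upsetting dreams",
    "Flashbacks",
    "Emotional cue activity",
    "Physiological cue reactivity",
    "Sleep disturbance",
    "Irritability",
    "Difficulty concentrating",
    "Hypervigilance",
    "Exaggerated startle response",
)


@dataclass(frozen=True)
class ItemSpec:
    """One questionnaire item: short node code, instrument, symptom label."""

    name: str
    instrument: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENT_LEVELS:
            raise ValidationError(
                f"unknown instrument {self.instrument!r} for item {self.name!r}"
            )

    @property
    def levels(self) -> range:
        lo, hi = INSTRUMENT_LEVELS[self.instrument]
        return range(lo, hi + 1)

    @property
    def n_levels(self) -> int:
        lo, hi = INSTRUMENT_LEVELS[self.instrument]
        return hi - lo + 1


def default_items() -> list[ItemSpec]:
    """The full 26-node battery: PHQ.1–9, GAD.1–7, PTSD.1–10."""
    items: list[ItemSpec] = []
    for i, label in enumerate(_PHQ9_LABELS, 1):
        items.append(ItemSpec(f"PHQ.{i}", "PHQ9", label))
    for i, label in enumerate(_GAD7_LABELS, 1):
        items.append(ItemSpec(f"GAD.{i}", "GAD7", label))
    for i, label in enumerate(_TSQ_LABELS, 1):
        items.append(ItemSpec(f"PTSD.{i}", "TSQ", label))
    return items


def items_for_nodes(nodes: Sequence[str]) -> list[ItemSpec]:
    """Build ItemSpecs from node codes like ``PHQ.3`` (instrument by prefix)."""
    items = []
    for name in nodes:
        prefix = name.split(".")[0]
        if prefix not in PREFIX_INSTRUMENT:
            raise SchemaError(f"cannot infer instrument for node {name!r}")
        items.append(ItemSpec(name, PREFIX_INSTRUMENT[prefix]))
    return items


def _check_instrument_counts(items: Sequence[ItemSpec]) -> None:
    counts: dict[str, int] = {}
    for it in items:
        counts[it.instrument] = counts.get(it.instrument, 0) + 1
    for inst, cnt in counts.items():
        if cnt != INSTRUMENT_SIZES[inst]:
            raise ValidationError(
                f"instrument {inst} has {cnt} items, expected {INSTRUMENT_SIZES[inst]}"
            )


@dataclass
class SymptomDataset:
    """Respondents × items integer score matrix with per-respondent group labels."""

    items: list[ItemSpec]
    scores: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        self.group = np.asarray(self.group, dtype=object)
        if self.scores.ndim != 2:
            raise ValidationError("scores must be a 2-D matrix")
        if self.scores.shape[1] != len(self.items):
            raise ValidationError(
                f"scores have {self.scores.shape[1]} columns for {len(self.items)} items"
            )
        if self.group.shape != (self.scores.shape[0],):
            raise ValidationError("group labels must align with score rows")
        if not np.issubdtype(self.scores.dtype, np.integer):
            as_int = self.scores.astype(np.int64)
            if not np.array_equal(as_int, self.scores):
                raise ValidationError("scores must be integers")
            self.scores = as_int
        self.validate_ranges()

    # -- invariants -----------------------------------------------------
    def validate_ranges(self) -> None:
        for j, item in enumerate(self.items):
            lo, hi = INSTRUMENT_LEVELS[item.instrument]
            col = self.scores[:, j]
            bad = np.where((col < lo) | (col > hi))[0]
            if bad.size:
                raise ValidationError(
                    f"item {item.name!r}: score {col[bad[0]]} out of range "
                    f"{lo}..{hi} at row {int(bad[0])}"
                )

    def validate_instruments(self) -> None:
        """Require complete instruments (9 + 7 + 10 items when all present)."""
        _check_instrument_counts(self.items)

    # -- accessors ------------------------------------------------------
    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def p(self) -> int:
        return self.scores.shape[1]

    @property
    def item_names(self) -> list[str]:
        return [it.name for it in self.items]

    def group_labels(self) -> list[str]:
        return sorted(set(self.group.tolist()))

    def subset(self, *groups: str) -> "SymptomDataset":
        """Rows belonging to the given group label(s), order preserved."""
        unknown = set(groups) - set(self.group.tolist())
        if unknown:
            raise ValidationError(f"unknown group label(s): {sorted(unknown)}")
        mask = np.isin(self.group, list(groups))
        return SymptomDataset(self.items, self.scores[mask], self.group[mask])

    def scale_total(self, instrument: str) -> np.ndarray:
        """Per-respondent sum score over one instrument's items."""
        cols = [j for j, it in enumerate(self.items) if it.instrument == instrument]
        if not cols:
            raise ValidationError(f"no items for instrument {instrument!r}")
        return self.scores[:, cols].sum(axis=1)

    def instrument_scores(self, instrument: str) -> np.ndarray:
        cols = [j for j, it in enumerate(self.items) if it.instrument == instrument]
        return self.scores[:, cols]

    # -- frames ---------------------------------------------------------
    def to_frame(self, group_column: str = "group") -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=self.item_names)
        df[group_column] = self.group
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        group_column: str = "group",
        items: Sequence[ItemSpec] | None = None,
    ) -> "SymptomDataset":
        if group_column not in df.columns:
            raise SchemaError(f"group column {group_column!r} not found")
        if items is None:
            items = items_for_nodes([c for c in df.columns if c != group_column])
        by_name = {it.name: it for it in items}
        unknown = [c for c in df.columns if c != group_column and c not in by_name]
        if unknown:
            raise SchemaError(f"unknown column(s): {unknown}")
        missing = [name for name in by_name if name not in df.columns]
        if missing:
            raise SchemaError(f"missing item column(s): {missing}")
        ordered = list(by_name)
        sub = df[ordered + [group_column]]
        n_raw = len(sub)
        sub = sub.dropna(axis=0, how="any")
        dropped = n_raw - len(sub)
        if dropped:
            logger.info("listwise deletion dropped %d of %d rows", dropped, n_raw)
        scores = sub[ordered].to_numpy()
        if not np.issubdtype(scores.dtype, np.integer):
            as_int = scores.astype(np.int64)
            if not np.array_equal(as_int, scores.astype(float)):
                raise ValidationError("non-integer item score encountered")
            scores = as_int
        return cls(list(items), scores, sub[group_column].to_numpy(dtype=object))


def concat_datasets(parts: Sequence[SymptomDataset]) -> SymptomDataset:
    """Stack datasets that share an item battery (row order = input order)."""
    first = parts[0]
    for other in parts[1:]:
        if other.item_names != first.item_names:
            raise ValidationError("datasets have different item batteries")
    scores = np.vstack([p.scores for p in parts])
    group = np.concatenate([p.group for p in parts])
    return SymptomDataset(first.items, scores, group)


def read_dataset(
    path: str | Path,
    group_column: str = "group",
    items: Sequence[ItemSpec] | None = None,
) -> SymptomDataset:
    """Read a wide CSV of item scores plus a group-label column.

    Rows with any missing item are removed (listwise deletion, logged).
    Raises :class:`SchemaError` for unknown/missing columns and
    :class:`ValidationError` for out-of-range scores (with the row index).
    """
    df = pd.read_csv(path)
    return SymptomDataset.from_frame(df, group_column=group_column, items=items)


def write_dataset(ds: SymptomDataset, path: str | Path, group_column: str = "group") -> None:
    ds.to_frame(group_column).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """Weighted undirected network over symptom nodes.

    ``weights`` is the symmetric p × p matrix of edge weights (partial
    correlations), zero diagonal, every |w| < 1.  ``metadata`` records
    the estimator settings that produced it (method, lambda, gamma, n).
    """

    nodes: list[str]
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        p = len(self.nodes)
        if self.weights.shape != (p, p):
            raise ValidationError(f"weight matrix shape {self.weights.shape} != ({p}, {p})")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValidationError("weight matrix is not symmetric")
        self.weights = 0.5 * (self.weights + self.weights.T)
        if np.any(np.abs(np.diag(self.weights)) > 1e-12):
            raise ValidationError("weight matrix diagonal must be zero")
        np.fill_diagonal(self.weights, 0.0)
        if np.any(np.abs(self.weights) >= 1.0):
            raise ValidationError("edge weights must satisfy |w| < 1")

    @property
    def p(self) -> int:
        return len(self.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        """Nonzero upper-triangle edges as (source, target, weight)."""
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0:
                    out.append((self.nodes[i], self.nodes[j], float(w)))
        return out


def write_network(net: Network, path: str | Path, fmt: str | None = None) -> None:
    """Write a network as edge-list CSV, JSON, or GraphML (by ``fmt`` or suffix).

    CSV holds only nonzero upper-triangle edges; JSON embeds the full
    weight matrix and metadata; GraphML stores a ``weight`` edge
    attribute.  JSON and GraphML round-trip weights at full precision.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        rows = [f"{s},{t},{w!r}" for s, t, w in net.edges()]
        path.write_text("source,target,weight\n" + "".join(r + "\n" for r in rows))
    elif fmt == "json":
        payload = {
            "nodes": list(net.nodes),
            "weights": [[float(w) for w in row] for row in net.weights],
            "metadata": net.metadata,
        }
        path.write_text(json.dumps(payload, indent=1))
    elif fmt == "graphml":
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        for s, t, w in net.edges():
            g.add_edge(s, t, weight=w)
        for key, val in net.metadata.items():
            g.graph[str(key)] = str(val)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, fmt: str | None = None) -> Network:
    """Read a network written by :func:`write_network`.

    The edge-list CSV format does not record isolated nodes; JSON or
    GraphML are the lossless round-trip formats.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "json":
        payload = json.loads(path.read_text())
        return Network(
            list(payload["nodes"]),
            np.asarray(payload["weights"], dtype=float),
            dict(payload.get("metadata", {})),
        )
    if fmt == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        nodes = list(g.nodes)
        idx = {node: k for k, node in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for s, t, attrs in g.edges(data=True):
            w[idx[s], idx[t]] = w[idx[t], idx[s]] = float(attrs["weight"])
        return Network(nodes, w, {k: v for k, v in g.graph.items()})
    if fmt == "csv":
        df = pd.read_csv(path)
        nodes = sorted(set(df["source"]) | set(df["target"]))
        idx = {node: k for k, node in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for _, row in df.iterrows():
            i, j = idx[row["source"]], idx[row["target"]]
            w[i, j] = w[j, i] = float(row["weight"])
        return Network(nodes, w)
    raise ValueError(f"unknown network format {fmt!r}")


# ---------------------------------------------------------------------------
# CTQ-SF subgroup assignment
# ---------------------------------------------------------------------------

#: moderate-severe cutoffs for the CTQ-SF abuse subscales
CTQ_CUTOFFS: Mapping[str, int] = {"EA": 13, "PA": 10, "SA": 8}


@dataclass(frozen=True)
class CTQScores:
    """CTQ-SF abuse subscale sums; each subscale has five 1–5 items (range 5–25)."""

    ea_score: int
    pa_score: int
    sa_score: int

    def __post_init__(self) -> None:
        for name in ("ea_score", "pa_score", "sa_score"):
            val = getattr(self, name)
            if not 5 <= val <= 25:
                raise ValidationError(f"{name}={val} outside the 5–25 subscale range")


def assign_ct_subgroup(scores: CTQScores) -> frozenset[str]:
    """Flags for moderate-severe abuse exposure: EA ≥ 13, PA ≥ 10, SA ≥ 8.

    Flags are independent; a respondent can carry several.  Allocating
    multi-flag respondents to disjoint analysis groups is the caller's
    decision.
    """
    flags = set()
    if scores.ea_score >= CTQ_CUTOFFS["EA"]:
        flags.add("EA")
    if scores.pa_score >= CTQ_CUTOFFS["PA"]:
        flags.add("PA")
    if scores.sa_score >= CTQ_CUTOFFS["SA"]:
        flags.add("SA")
    return frozenset(flags)
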