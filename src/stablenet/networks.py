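"""Daily contact networks, centrality, and mixing heat maps.

Contact events are aggregated into one undirected weighted graph per 24-h
period; an edge's weight is the pair's total contact duration in hours for
that day, and an event contributes its whole duration to the day bin of its
start time (the firmware sorts records by contact start date).  On top of
the daily graphs the module computes the node-level measures used to
characterise livestock contact structure -- unweighted degree, strength
(weighted degree, in hours) and eigenvector centrality -- plus heat-map
matrices and a within/between-group mixing ratio that quantifies how far a
network departs from homogeneous mixing.
"""

from __future__ import annotations

import csv
import math
import os
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .facility_sim import DAY_S, Pair, _ordered
from .ingest_clean import ContactEvent

NODE_KINDS = ("horse", "person", "location", "bookkeeping")

#: packaged fixture: printed horse-horse contact-duration matrix (hours);
#: lower triangle = study day 1, upper triangle = a later study day
DAY1_MATRIX_RESOURCE = "horse_contact_hours_day1_day3.csv"


@dataclass
class DailyNetwork:
    """Undirected weighted contact graph for one 24-hour bin.

    Nodes carry a ``kind`` attribute (horse/person/location/bookkeeping);
    edge weights are total contact hours for the day.
    """

    day_index: int
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self):
        for u, v, w in self.graph.edges(data="weight_hours"):
            if u == v:
                raise ValueError("self-edge in daily network")
            if w is None or w < 0:
                raise ValueError("edge weights must be nonnegative hours")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def nodes_of_kind(self, kind: Optional[str]) -> List[str]:
        if kind is None:
            return sorted(self.graph.nodes)
        return sorted(n for n, k in self.graph.nodes(data="kind")
                      if k == kind)

    def subgraph_of_kind(self, kind: Optional[str]) -> "DailyNetwork":
        if kind is None:
            return self
        sub = self.graph.subgraph(self.nodes_of_kind(kind)).copy()
        return DailyNetwork(day_index=self.day_index, graph=sub)

    def weight(self, a: str, b: str) -> float:
        if self.graph.has_edge(a, b):
            return self.graph[a][b]["weight_hours"]
        return 0.0

    def total_hours(self) -> float:
        return sum(w for _, _, w in
                   self.graph.edges(data="weight_hours"))

    @classmethod
    def from_edges(cls, day_index: int,
                   edges: Iterable[Tuple[str, str, float]],
                   node_kinds: Optional[Mapping[str, str]] = None,
                   nodes: Iterable[str] = ()) -> "DailyNetwork":
        g = nx.Graph()
        node_kinds = node_kinds or {}
        for n in nodes:
            g.add_node(n, kind=node_kinds.get(n, "horse"))
        for a, b, w in edges:
            a, b = _ordered(a, b)
            if g.has_edge(a, b):
                g[a][b]["weight_hours"] += float(w)
            else:
                g.add_edge(a, b, weight_hours=float(w))
        for n in g.nodes:
            g.nodes[n].setdefault("kind", node_kinds.get(n, "horse"))
        return cls(day_index=day_index, graph=g)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_daily(events: Sequence[ContactEvent],
                    day_length_s: int = DAY_S,
                    first_day_start: int = 0,
                    n_days: Optional[int] = None,
                    node_kinds: Optional[Mapping[str, str]] = None,
                    split_credit: bool = False) -> List[DailyNetwork]:
    """Aggregate wall-clock contact events into daily weighted networks.

    By default an event's whole duration is credited to the day bin of its
    start time; with ``split_credit=True`` the duration is split across the
    bins the event actually spans (a sensitivity-analysis alternative).
    Returns one network per day (1-based day index), including empty days.
    """
    if day_length_s <= 0:
        raise ValueError("day_length_s must be positive")
    if n_days is None:
        if events:
            last = max(ev.end_wall_s for ev in events)
            n_days = max(1, (last - first_day_start) // day_length_s + 1)
        else:
            n_days = 1
    weights: Dict[int, Dict[Pair, float]] = {d: {} for d in
                                             range(1, n_days + 1)}
    for ev in events:
        if not split_credit:
            d = (ev.start_wall_s - first_day_start) // day_length_s + 1
            if d in weights:
                weights[d][ev.pair] = (weights[d].get(ev.pair, 0.0)
                                       + ev.duration_s / 3600.0)
        else:
            s, e = ev.start_wall_s, ev.end_wall_s
            d_first = (s - first_day_start) // day_length_s
            d_last = (max(s, e - 1) - first_day_start) // day_length_s
            for db in range(d_first, d_last + 1):
                lo = first_day_start + db * day_length_s
                hi = lo + day_length_s
                part = min(e, hi) - max(s, lo)
                d = db + 1
                if part > 0 and d in weights:
                    weights[d][ev.pair] = (weights[d].get(ev.pair, 0.0)
                                           + part / 3600.0)
    return [DailyNetwork.from_edges(d, [(a, b, w) for (a, b), w in
                                        sorted(weights[d].items())],
                                    node_kinds=node_kinds)
            for d in sorted(weights)]


DAILY_CSV_COLUMNS = ("source_internal_id", "partner_internal_id",
                     "weight_hours")


def write_daily_csv(networks: Sequence[DailyNetwork], directory,
                    id_map: Optional[Mapping[str, Union[int, str]]] = None
                    ) -> List[str]:
    """Write one edge-list CSV per day (``day<N>.csv``), pair-sorted, with
    columns source_internal_id,partner_internal_id,weight_hours.

    ``id_map`` maps node ids to the internal IDs written in the file
    (defaults to the node ids themselves)."""
    if not networks:
        raise ValueError("no networks to write")
    os.makedirs(directory, exist_ok=True)
    id_map = dict(id_map) if id_map else {}
    paths = []
    for net in networks:
        path = os.path.join(directory, f"day{net.day_index}.csv")
        rows = sorted((str(id_map.get(a, a)), str(id_map.get(b, b)),
                       repr(float(w)))
                      for a, b, w in net.graph.edges(data="weight_hours"))
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(DAILY_CSV_COLUMNS)
            w.writerows(rows)
        paths.append(path)
    return paths


def read_daily_csv(path, day_index: Optional[int] = None,
                   node_kinds: Optional[Mapping[str, str]] = None
                   ) -> DailyNetwork:
    if day_index is None:
        m = re.search(r"day(\d+)", os.path.basename(str(path)))
        day_index = int(m.group(1)) if m else 1
    edges = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            edges.append((row["source_internal_id"],
                          row["partner_internal_id"],
                          float(row["weight_hours"])))
    return DailyNetwork.from_edges(day_index, edges, node_kinds=node_kinds)


# ---------------------------------------------------------------------------
# Printed triangular matrices
# ---------------------------------------------------------------------------

BELOW_DETECT_TOKEN = "<0.00"
BELOW_DETECT_POLICIES = ("edge_weight_zero", "drop")


def load_contact_matrix(source, triangle: str = "lower",
                        below_detect_policy: str = "edge_weight_zero",
                        day_index: int = 1,
                        node_kind: str = "horse") -> DailyNetwork:
    """Parse a printed square contact-duration matrix into a network.

    ``source`` is a CSV path or file-like object: a labelled square matrix
    whose cells are empty (no recorded contact), numeric hours, or the
    token ``"<0.00"`` marking a recorded contact of negligible duration.
    Only the selected ``triangle`` is read.  ``below_detect_policy``
    controls the ``"<0.00"`` cells: ``edge_weight_zero`` (default) keeps
    the edge with weight 0; ``drop`` omits it.
    """
    if triangle not in ("lower", "upper"):
        raise ValueError("triangle must be 'lower' or 'upper'")
    if below_detect_policy not in BELOW_DETECT_POLICIES:
        raise ValueError(f"unknown policy {below_detect_policy!r}")
    df = pd.read_csv(source, index_col=0, dtype=str)
    labels = [str(x).strip() for x in df.index]
    cols = [str(x).strip() for x in df.columns]
    if labels != cols:
        raise ValueError("matrix row and column labels differ "
                         f"({labels} vs {cols})")
    edges: List[Tuple[str, str, float]] = []
    n = len(labels)
    for i in range(n):
        for j in range(n):
            take = (i > j) if triangle == "lower" else (i < j)
            if not take:
                continue
            cell = df.iat[i, j]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell == "":
                continue
            if cell == BELOW_DETECT_TOKEN:
                if below_detect_policy == "edge_weight_zero":
                    edges.append((labels[i], labels[j], 0.0))
                continue
            try:
                w = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric cell {cell!r} at ({labels[i]}, "
                    f"{labels[j]})") from exc
            edges.append((labels[i], labels[j], w))
    kinds = {lab: node_kind for lab in labels}
    return DailyNetwork.from_edges(day_index, edges, node_kinds=kinds,
                                   nodes=labels)


def day1_horse_network(below_detect_policy: str = "edge_weight_zero"
                       ) -> DailyNetwork:
    """The packaged day-1 horse-horse network (lower triangle of the
    printed contact-duration matrix): 9 horses, 27 recorded pairs."""
    ref = resources.files("stablenet").joinpath("data",
                                                DAY1_MATRIX_RESOURCE)
    with ref.open("r") as fh:
        return load_contact_matrix(fh, triangle="lower",
                                   below_detect_policy=below_detect_policy,
                                   day_index=1)


# ---------------------------------------------------------------------------
# Centrality
# ---------------------------------------------------------------------------

@dataclass
class CentralityReport:
    """Per-node degree, strength (hours) and eigenvector centrality."""

    day_index: int
    degree: Dict[str, int]
    strength: Dict[str, float]
    eigenvector: Dict[str, float]
    disconnected: bool = False

    @property
    def nodes(self) -> List[str]:
        return sorted(self.degree)

    def mean_degree(self) -> float:
        return float(np.mean([self.degree[n] for n in self.nodes]))

    def max_degree(self) -> int:
        return max(self.degree.values())

    def max_strength(self) -> float:
        return max(self.strength.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"degree": self.degree, "strength": self.strength,
             "eigenvector": self.eigenvector}).loc[self.nodes]


def centrality(network: DailyNetwork,
               restrict_to_type: Optional[str] = None) -> CentralityReport:
    """Compute degree, strength, and eigenvector centrality.

    Degree is the incident edge count (0..N-1); strength the incident
    weight sum in hours (it may exceed 24 h since a node can be in contact
    with several partners simultaneously).  Eigenvector centrality is the
    principal eigenvector of the weighted adjacency matrix, entries
    nonnegative and normalised to unit Euclidean norm, hence in [0, 1].
    Disconnected graphs are handled per connected component (each
    component's sub-vector has unit norm; isolated nodes score 0) and the
    report is flagged.
    """
    net = network.subgraph_of_kind(restrict_to_type)
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network after type restriction")
    degree = {n: int(d) for n, d in g.degree()}
    strength = {n: float(s) for n, s in g.degree(weight="weight_hours")}
    eigen: Dict[str, float] = {n: 0.0 for n in g.nodes}
    components = list(nx.connected_components(g))
    for comp in components:
        nodes = sorted(comp)
        if len(nodes) == 1:
            continue
        a = nx.to_numpy_array(g, nodelist=nodes, weight="weight_hours")
        if not a.any():
            # all incident weights zero: fall back to the unweighted
            # skeleton so the component still has a Perron vector
            a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
        vals, vecs = np.linalg.eigh(a)
        v = vecs[:, int(np.argmax(vals))]
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        norm = np.linalg.norm(v)
        if norm > 0:
            v = v / norm
        for n, x in zip(nodes, v):
            eigen[n] = float(x)
    return CentralityReport(day_index=network.day_index, degree=degree,
                            strength=strength, eigenvector=eigen,
                            disconnected=len(components) > 1)


# ---------------------------------------------------------------------------
# Heat maps and mixing
# ---------------------------------------------------------------------------

@dataclass
class HeatMapMatrix:
    """Symmetric total-contact-hours matrix over tags or tag types."""

    labels: List[str]
    matrix: np.ndarray
    level: str  # "tag" | "tag_type"
    grouping: Dict[str, str] = field(default_factory=dict)

    def cell(self, x: str, y: str) -> float:
        i, j = self.labels.index(x), self.labels.index(y)
        return float(self.matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels,
                            columns=self.labels)


def heatmap_matrix(network: DailyNetwork, level: str = "tag",
                   grouping: Optional[Mapping[str, str]] = None
                   ) -> HeatMapMatrix:
    """Build the contact heat-map matrix of a network.

    At ``tag`` level, entry (i, j) is the pair's contact hours (diagonal
    zero, no self-contacts) and rows are ordered by the grouping annotation
    (e.g. pasture or aisle), then by id.  At ``tag_type`` level, entry
    (X, Y) is the total hours between all tags of kind X and kind Y (the
    diagonal holds within-type totals).
    """
    g = network.graph
    if level == "tag":
        grouping = dict(grouping or {})
        unknown = set(grouping) - set(g.nodes)
        if unknown:
            raise ValueError(f"grouping references unknown nodes: "
                             f"{sorted(unknown)}")
        labels = sorted(g.nodes,
                        key=lambda n: (grouping.get(n, ""), str(n)))
        a = nx.to_numpy_array(g, nodelist=labels, weight="weight_hours")
        np.fill_diagonal(a, 0.0)
        return HeatMapMatrix(labels=labels, matrix=a, level="tag",
                             grouping=grouping)
    elif level == "tag_type":
        kinds = sorted({k for _, k in g.nodes(data="kind") if k})
        idx = {k: i for i, k in enumerate(kinds)}
        a = np.zeros((len(kinds), len(kinds)))
        for u, v, w in g.edges(data="weight_hours"):
            ku, kv = g.nodes[u].get("kind"), g.nodes[v].get("kind")
            if ku is None or kv is None:
                raise ValueError("node without kind at tag_type level")
            a[idx[ku], idx[kv]] += w
            if ku != kv:
                a[idx[kv], idx[ku]] += w
        return HeatMapMatrix(labels=kinds, matrix=a, level="tag_type",
                             grouping={k: k for k in kinds})
    raise ValueError(f"unknown level {level!r}")


@dataclass
class MixingSummary:
    """Within/between-group mean cell weights and their ratio.

    Under homogeneous mixing the ratio is ~1; a large ratio (or an exactly
    zero between-group mean, reported via ``between_zero``) indicates
    block-structured, non-homogeneous contact patterns.
    """

    within_mean: float
    between_mean: float
    ratio: float
    between_zero: bool

    @property
    def homogeneous(self) -> bool:
        """Rule-of-thumb flag: ratio within [0.8, 1.25] and both means
        positive."""
        return (not self.between_zero and self.within_mean > 0
                and 0.8 <= self.ratio <= 1.25)


def mixing_summary(matrix: HeatMapMatrix,
                   grouping: Optional[Mapping[str, str]] = None
                   ) -> MixingSummary:
    """Quantify departure from homogeneous mixing on a tag-level heat map:
    mean within-group cell over mean between-group cell."""
    grouping = dict(grouping or matrix.grouping)
    missing = [lab for lab in matrix.labels if lab not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover nodes: {missing}")
    groups = {grouping[lab] for lab in matrix.labels}
    if len(groups) < 2:
        raise ValueError("mixing ratio needs at least two groups")
    within: List[float] = []
    between: List[float] = []
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            cell = float(matrix.matrix[i, j])
            if grouping[matrix.labels[i]] == grouping[matrix.labels[j]]:
                within.append(cell)
            else:
                between.append(cell)
    w = float(np.mean(within)) if within else 0.0
    b = float(np.mean(between)) if between else 0.0
    if b == 0.0:
        return MixingSummary(within_mean=w, between_mean=0.0,
                             ratio=math.inf, between_zero=True)
    return MixingSummary(within_mean=w, between_mean=b, ratio=w / b,
                         between_zero=False)


def render_heatmap(matrix: HeatMapMatrix, path) -> None:
    """Optional cosmetic PNG rendering of a heat-map matrix (requires
    matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.matrix, cmap="viridis")
    ax.set_xticks(range(len(matrix.labels)), matrix.labels, rotation=90,
                  fontsize=7)
    ax.set_yticks(range(len(matrix.labels)), matrix.labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="contact hours")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
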