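"""Survey-predicted networks and predicted-vs-observed classification.

A facility-management survey gives each horse's barn (aisle) and pasture
assignment.  Assuming every pair of horses that shares a pasture or a barn
class came into contact yields a predicted, unweighted "survey-based"
network: the union of complete graphs over each grouping class.  Treating
the unweighted tag-derived network as the gold standard and the survey
network as a diagnostic test, a 2x2 classification table over unordered
horse pairs gives sensitivity, specificity, and positive/negative
predictive values of management data as a stand-in for sensor data.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import networkx as nx

from .facility_sim import Pair, Scenario, _ordered
from .networks import DailyNetwork


@dataclass(frozen=True)
class SurveyMembership:
    """Survey answers for one horse: its barn class (whole barn or aisle,
    per the configured granularity) and pasture class; ``pasture_days``
    carries per-pasture day counts when the horse moved during the week."""

    horse_id: str
    pasture_class: Optional[str] = None
    barn_class: Optional[str] = None
    pasture_days: Mapping[str, int] = None  # type: ignore[assignment]


class MembershipError(ValueError):
    """Raised when a horse lacks a required survey membership."""


@dataclass
class SurveyNetwork:
    """Unweighted predicted contact graph: union of within-class complete
    graphs over pasture classes and barn classes."""

    graph: nx.Graph

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> Set[Pair]:
        return {_ordered(u, v) for u, v in self.graph.edges}


def _majority_pasture(m: SurveyMembership) -> str:
    if m.pasture_days:
        # majority rule; ties broken towards the lexicographically first
        # class for determinism
        best = sorted(m.pasture_days.items(),
                      key=lambda kv: (-kv[1], kv[0]))[0][0]
        return best
    if m.pasture_class is None:
        raise MembershipError(f"horse {m.horse_id!r} has no pasture class")
    return m.pasture_class


def build_survey_network(memberships: Union[
        Mapping[str, Mapping], Sequence[SurveyMembership]],
        majority_rule: bool = True) -> SurveyNetwork:
    """Build the survey-based predicted network from group memberships.

    ``memberships`` is either a sequence of :class:`SurveyMembership` or a
    mapping ``horse_id -> {"pasture_class": ..., "barn_class": ...,
    ["pasture_days": {...}]}``.  A horse turned out in several pastures
    during the week is assigned the pasture it occupied the majority of
    days (``majority_rule=True``; otherwise ``pasture_class`` must be
    explicit).  Horses sharing a pasture class or a barn class are joined
    by an edge.
    """
    ms: List[SurveyMembership] = []
    if isinstance(memberships, Mapping):
        for hid, rec in memberships.items():
            ms.append(SurveyMembership(
                horse_id=hid,
                pasture_class=rec.get("pasture_class"),
                barn_class=rec.get("barn_class"),
                pasture_days=rec.get("pasture_days")))
    else:
        ms = list(memberships)

    g = nx.Graph()
    pasture_of: Dict[str, str] = {}
    barn_of: Dict[str, str] = {}
    for m in ms:
        if m.barn_class is None:
            raise MembershipError(f"horse {m.horse_id!r} has no barn class")
        if majority_rule:
            pasture_of[m.horse_id] = _majority_pasture(m)
        else:
            if m.pasture_class is None:
                raise MembershipError(
                    f"horse {m.horse_id!r} has no pasture class")
            pasture_of[m.horse_id] = m.pasture_class
        barn_of[m.horse_id] = m.barn_class
        g.add_node(m.horse_id)
    for a, b in itertools.combinations(sorted(g.nodes), 2):
        if pasture_of[a] == pasture_of[b] or barn_of[a] == barn_of[b]:
            g.add_edge(a, b)
    return SurveyNetwork(graph=g)


def memberships_from_scenario(scenario: Scenario,
                              barn_granularity: str = "aisle"
                              ) -> List[SurveyMembership]:
    """Derive survey memberships from a simulated scenario.

    ``barn_granularity`` selects the barn class definition: ``"aisle"``
    (default; same-aisle horses share a class, matching observed same-aisle
    proximity) or ``"barn"`` (every horse shares one class, which makes the
    predicted network complete).
    """
    if barn_granularity not in ("aisle", "barn"):
        raise ValueError("barn_granularity must be 'aisle' or 'barn'")
    occ = scenario.pasture_occupancy()
    out = []
    for h in scenario.horses:
        barn = h.aisle if barn_granularity == "aisle" else "barn"
        out.append(SurveyMembership(horse_id=h.id,
                                    pasture_class=h.weekday_pasture,
                                    barn_class=barn,
                                    pasture_days=occ[h.id]))
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationTable:
    """2x2 confusion counts over unordered node pairs.

    Gold = tag-derived (observed) edges, test = survey-predicted edges.
    Metrics undefined by a 0/0 division are NaN, never coerced to 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    @property
    def sn(self) -> float:
        """Sensitivity tp/(tp+fn): predicted share of observed contacts."""
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def sp(self) -> float:
        """Specificity tn/(tn+fp): predicted share of observed absences."""
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def n_pairs(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


GraphLike = Union[nx.Graph, DailyNetwork, SurveyNetwork]


def _as_graph(net: GraphLike) -> nx.Graph:
    if isinstance(net, DailyNetwork):
        return net.graph
    if isinstance(net, SurveyNetwork):
        return net.graph
    return net


def classify(gold: GraphLike, test: GraphLike,
             nodes: Optional[Iterable[str]] = None) -> ClassificationTable:
    """Score a predicted network against an observed one over unordered
    node pairs.

    Both networks are treated as unweighted.  ``nodes`` optionally
    restricts the pair universe (e.g. to horses); otherwise the two node
    sets must be identical.
    """
    g, t = _as_graph(gold), _as_graph(test)
    if nodes is None:
        if set(g.nodes) != set(t.nodes):
            raise ValueError(
                "gold and test node sets differ; pass nodes= to restrict")
        universe = sorted(g.nodes)
    else:
        universe = sorted(nodes)
        for name, net in (("gold", g), ("test", t)):
            missing = set(universe) - set(net.nodes)
            if missing:
                raise ValueError(f"{name} network lacks nodes "
                                 f"{sorted(missing)}")
    gold_edges = {_ordered(u, v) for u, v in g.edges
                  if u in set(universe) and v in set(universe)}
    test_edges = {_ordered(u, v) for u, v in t.edges
                  if u in set(universe) and v in set(universe)}
    tp = fp = tn = fn = 0
    for a, b in itertools.combinations(universe, 2):
        pair = (a, b)
        in_gold = pair in gold_edges
        in_test = pair in test_edges
        if in_gold and in_test:
            tp += 1
        elif in_test:
            fp += 1
        elif in_gold:
            fn += 1
        else:
            tn += 1
    return ClassificationTable(tp=tp, fp=fp, tn=tn, fn=fn)


def weekly_combined(networks: Sequence[DailyNetwork]) -> nx.Graph:
    """Union of daily networks as an unweighted graph: a pair is joined iff
    it has an edge on any study day."""
    g = nx.Graph()
    for net in networks:
        g.add_nodes_from(net.graph.nodes(data=True))
        for u, v in net.graph.edges:
            g.add_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# Interchange
# ---------------------------------------------------------------------------

MEMBERSHIP_COLUMNS = ("horse_id", "pasture_class", "barn_class")


def read_memberships_csv(path) -> List[SurveyMembership]:
    """Read a memberships CSV: horse_id,pasture_class,barn_class plus any
    number of per-pasture day-count columns named ``days_<pasture>``."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            days = {k[len("days_"):]: int(v) for k, v in row.items()
                    if k.startswith("days_") and v not in ("", None)}
            out.append(SurveyMembership(
                horse_id=row["horse_id"],
                pasture_class=row.get("pasture_class") or None,
                barn_class=row.get("barn_class") or None,
                pasture_days=days or None))
    return out


def write_classification_csv(tables: Mapping[Union[int, str],
                                             ClassificationTable],
                             path) -> None:
    """Write per-day (and combined) classification rows:
    day,tp,fp,tn,fn,sn,sp,ppv,npv.  Undefined metrics are left blank."""

    def fmt(x: float) -> str:
        return "" if math.isnan(x) else f"{x:.4f}"

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["day", "tp", "fp", "tn", "fn", "sn", "sp", "ppv", "npv"])
        for day, t in tables.items():
            w.writerow([day, t.tp, t.fp, t.tn, t.fn,
                        fmt(t.sn), fmt(t.sp), fmt(t.ppv), fmt(t.npv)])
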