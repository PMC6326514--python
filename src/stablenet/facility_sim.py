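"""Synthetic facility scenarios and ground-truth proximity streams.

This module generates per-second "within detection range" indicator data for
every pair of proximity tags in a boarding-stable scenario: horses wearing
halter-mounted tags, staff wearing tags on lanyards during their shifts,
static tags fixed at facility locations, and one stationary bookkeeping tag
that collects the tags not currently in use.  The schedule model is
deliberately simple -- schedule-driven co-location states, not animal
movement -- and is meant as a ground truth against which the tag-firmware
emulator and the downstream cleaning/network pipeline can be validated.

Key behavioural rules:

* Overnight, horses stand in their stalls; same-aisle neighbours meet in
  alternating exponential on/off bouts.
* During turnout (default 08:30-16:30) the halters are removed and hung
  together on a hook on the pasture fence, so all halter tags of horses
  sharing a pasture are continuously mutually in range, and in range of that
  pasture's static tag.
* Walking to/from pasture puts a horse tag briefly in range of the barn-door
  and aisle tags.
* Evening training/grooming bouts put a horse in range of an activity
  location tag (arena, wash stall, cross-ties) and, when one is on shift, a
  handler's tag.
* Off shift, person tags sit with the bookkeeping tag and are continuously
  in range of it.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

DAY_S = 86_400
WEEKDAYS = ("monday", "tuesday", "wednesday", "thursday", "friday",
            "saturday", "sunday")

Pair = Tuple[str, str]
Interval = Tuple[int, int]  # half-open [start, end) in wall-clock seconds


def _ordered(a: str, b: str) -> Pair:
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


def _merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Merge overlapping/adjacent half-open intervals into a sorted list."""
    out: List[Interval] = []
    for s, e in sorted(intervals):
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def _clip(intervals: Sequence[Interval], lo: int, hi: int) -> List[Interval]:
    return [(max(s, lo), min(e, hi)) for s, e in intervals
            if min(e, hi) > max(s, lo)]


def _stable_int(*keys) -> int:
    """Deterministic 32-bit stream key from mixed str/int keys."""
    h = 0
    for k in keys:
        h = zlib.crc32(repr(k).encode(), h)
    return h & 0x7FFF_FFFF


def _rng(seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFF_FFFF, _stable_int(*keys)])


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Horse:
    id: str
    stall: str
    aisle: str
    weekday_pasture: str
    weekend_pasture: str
    use_label: str = "pleasure"


@dataclass(frozen=True)
class Person:
    id: str
    #: daily shift windows as clock-time seconds since midnight, half-open
    shifts: Tuple[Interval, ...] = ((8 * 3600, 17 * 3600),)


@dataclass(frozen=True)
class StaticTag:
    id: str
    location_label: str


class ScenarioError(ValueError):
    """Raised when a scenario description fails validation."""


@dataclass(frozen=True)
class Scenario:
    """A complete description of a tag deployment at one facility.

    Time is integer wall-clock seconds from deployment start (midnight of
    day 1); clock granularity is 1 s everywhere, matching 1 Hz tag sensing.
    Days are numbered 1..n_days.
    """

    horses: Tuple[Horse, ...]
    people: Tuple[Person, ...] = ()
    static_tags: Tuple[StaticTag, ...] = ()
    bookkeeping_tag_id: str = "bookkeeping"
    n_days: int = 7
    day0_weekday: str = "tuesday"
    turnout_window: Interval = (8 * 3600 + 30 * 60, 16 * 3600 + 30 * 60)
    seed: int = 0
    #: days (1-based) on which horses occupy their weekend pasture
    weekend_move_days: Tuple[int, ...] = (4, 5)
    # free parameters of the bout model (seconds)
    stall_bout_mean_on_s: float = 600.0
    stall_bout_mean_off_s: float = 3600.0
    transit_s: int = 60
    training_bouts_per_day: float = 1.0
    training_bout_mean_s: float = 1800.0
    person_transits_per_shift: float = 2.0

    def __post_init__(self):
        ids = ([h.id for h in self.horses] + [p.id for p in self.people]
               + [t.id for t in self.static_tags] + [self.bookkeeping_tag_id])
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ScenarioError(f"duplicate tag ids: {sorted(dupes)}")
        stalls = [h.stall for h in self.horses]
        if len(set(stalls)) != len(stalls):
            raise ScenarioError("two horses share one stall id")
        for h in self.horses:
            if not (h.stall and h.aisle and h.weekday_pasture):
                raise ScenarioError(
                    f"horse {h.id!r} missing stall/aisle/pasture assignment")
        if not self.turnout_window[0] < self.turnout_window[1]:
            raise ScenarioError("turnout start must precede turnout end")
        if self.n_days < 1:
            raise ScenarioError("n_days must be >= 1")
        if self.day0_weekday not in WEEKDAYS:
            raise ScenarioError(f"unknown weekday {self.day0_weekday!r}")

    # -- derived views ------------------------------------------------------

    @property
    def tag_ids(self) -> Tuple[str, ...]:
        return tuple([h.id for h in self.horses] + [p.id for p in self.people]
                     + [t.id for t in self.static_tags]
                     + [self.bookkeeping_tag_id])

    def roles(self) -> Dict[str, str]:
        roles = {h.id: "horse" for h in self.horses}
        roles.update({p.id: "person" for p in self.people})
        roles.update({t.id: "location" for t in self.static_tags})
        roles[self.bookkeeping_tag_id] = "bookkeeping"
        return roles

    def pasture_of(self, horse: Horse, day: int) -> str:
        if day in self.weekend_move_days:
            return horse.weekend_pasture
        return horse.weekday_pasture

    def pasture_occupancy(self) -> Dict[str, Dict[str, int]]:
        """Per-horse day counts in each pasture over the whole deployment."""
        occ: Dict[str, Dict[str, int]] = {}
        for h in self.horses:
            counts: Dict[str, int] = {}
            for day in range(1, self.n_days + 1):
                p = self.pasture_of(h, day)
                counts[p] = counts.get(p, 0) + 1
            occ[h.id] = counts
        return occ

    def total_seconds(self) -> int:
        return self.n_days * DAY_S


def build_scenario(config: Mapping) -> Scenario:
    """Build and validate a :class:`Scenario` from a plain config mapping.

    The mapping mirrors the YAML/JSON schema shipped with the package
    (``scenario_schema()``): ``horses`` is a list of mappings with keys
    ``id, stall, aisle, weekday_pasture[, weekend_pasture, use_label]``;
    ``people`` a list with ``id[, shifts]`` where shifts are
    ``[[start_s, end_s], ...]`` clock windows; ``static_tags`` a list with
    ``id[, location_label]``.  Remaining keys map directly onto Scenario
    fields.
    """
    cfg = dict(config)
    horses = []
    for h in cfg.pop("horses", []):
        h = dict(h)
        h.setdefault("weekend_pasture", h.get("weekday_pasture"))
        horses.append(Horse(**h))
    people = []
    for p in cfg.pop("people", []):
        p = dict(p)
        if "shifts" in p:
            p["shifts"] = tuple(tuple(w) for w in p["shifts"])
        people.append(Person(**p))
    statics = [StaticTag(**dict(t)) for t in cfg.pop("static_tags", [])]
    if "turnout_window" in cfg:
        cfg["turnout_window"] = tuple(cfg["turnout_window"])
    if "weekend_move_days" in cfg:
        cfg["weekend_move_days"] = tuple(cfg["weekend_move_days"])
    try:
        return Scenario(horses=tuple(horses), people=tuple(people),
                        static_tags=tuple(statics), **cfg)
    except TypeError as exc:  # unknown keys etc.
        raise ScenarioError(str(exc)) from exc


def load_scenario(path) -> Scenario:
    """Load a scenario from a YAML or JSON config file (YAML is a JSON
    superset here; both parse through the same loader)."""
    import yaml

    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ScenarioError("scenario config must be a mapping")
    return build_scenario(config)


def scenario_schema() -> Dict:
    """A minimal JSON-schema-style description of the scenario config."""
    return {
        "type": "object",
        "properties": {
            "horses": {"type": "array", "items": {
                "type": "object",
                "required": ["id", "stall", "aisle", "weekday_pasture"],
            }},
            "people": {"type": "array"},
            "static_tags": {"type": "array"},
            "bookkeeping_tag_id": {"type": "string"},
            "n_days": {"type": "integer", "minimum": 1},
            "day0_weekday": {"enum": list(WEEKDAYS)},
            "turnout_window": {"type": "array"},
            "weekend_move_days": {"type": "array"},
            "seed": {"type": "integer"},
        },
        "required": ["horses"],
    }


#: the 17 static locations of the default facility
_DEFAULT_LOCATIONS = (
    "pasture_1", "pasture_2", "pasture_3", "pasture_4",
    "barn_door", "aisle_a", "aisle_b",
    "arena_indoor", "arena_outdoor",
    "wash_stall", "grooming_stall",
    "cross_ties_1", "cross_ties_2",
    "tack_room", "feed_room",
    "farm_entrance_1", "farm_entrance_2",
)

#: evening activity locations a horse may visit for training/grooming
_ACTIVITY_LOCATIONS = ("arena_indoor", "arena_outdoor", "wash_stall",
                       "grooming_stall", "cross_ties_1", "cross_ties_2")


def default_scenario(n_days: int = 7, seed: int = 0,
                     weekend_move: bool = True) -> Scenario:
    """The default boarding-stable deployment: 9 horses in two barn aisles,
    6 staff, 17 static location tags and one bookkeeping tag (33 tags), over
    a 7-day Tuesday-start week with turnout 08:30-16:30, and at least one
    horse moved to a fourth pasture on days 4-5 (the weekend move).
    """
    uses = ("lessons", "lessons", "lessons", "lessons",
            "dressage", "dressage", "dressage", "field_hunting",
            "field_hunting")
    horses = []
    for i in range(1, 10):
        aisle = "aisle_a" if i <= 5 else "aisle_b"
        weekday_pasture = f"pasture_{(i - 1) // 3 + 1}"
        weekend_pasture = weekday_pasture
        if weekend_move and i == 9:
            weekend_pasture = "pasture_4"
        horses.append(Horse(id=f"horse_{i}", stall=f"stall_{i}", aisle=aisle,
                            weekday_pasture=weekday_pasture,
                            weekend_pasture=weekend_pasture,
                            use_label=uses[i - 1]))
    shifts = [((7 * 3600, 12 * 3600), (13 * 3600, 17 * 3600)),
              ((7 * 3600, 15 * 3600),),
              ((8 * 3600, 17 * 3600),),
              ((9 * 3600, 18 * 3600),),
              ((12 * 3600, 20 * 3600),),
              ((8 * 3600, 13 * 3600),)]
    people = [Person(id=f"person_{j + 1}", shifts=shifts[j])
              for j in range(6)]
    statics = [StaticTag(id=loc, location_label=loc)
               for loc in _DEFAULT_LOCATIONS]
    return Scenario(horses=tuple(horses), people=tuple(people),
                    static_tags=tuple(statics), n_days=n_days, seed=seed)


# ---------------------------------------------------------------------------
# Proximity stream
# ---------------------------------------------------------------------------

@dataclass
class ProximityStream:
    """Ground-truth per-second in-range indicators for unordered tag pairs.

    Stored internally as merged half-open second-intervals per pair; the
    per-second sample view is available via :meth:`iter_samples` and
    :meth:`pair_seconds`.
    """

    total_seconds: int
    intervals: Dict[Pair, List[Interval]] = field(default_factory=dict)

    def __post_init__(self):
        clean: Dict[Pair, List[Interval]] = {}
        for (a, b), ivs in self.intervals.items():
            merged = _clip(_merge_intervals(ivs), 0, self.total_seconds)
            if merged:
                clean[_ordered(a, b)] = merged
        self.intervals = clean

    @classmethod
    def from_samples(cls, samples: Iterable[Tuple[int, str, str]],
                     total_seconds: int) -> "ProximityStream":
        by_pair: Dict[Pair, List[Interval]] = {}
        for sec, a, b in samples:
            by_pair.setdefault(_ordered(a, b), []).append((sec, sec + 1))
        return cls(total_seconds=total_seconds, intervals=by_pair)

    @property
    def pairs(self) -> List[Pair]:
        return sorted(self.intervals)

    @property
    def tags(self) -> List[str]:
        return sorted({t for pair in self.intervals for t in pair})

    def pair_intervals(self, a: str, b: str) -> List[Interval]:
        return list(self.intervals.get(_ordered(a, b), []))

    def pair_seconds(self, a: str, b: str) -> np.ndarray:
        """All wall-clock seconds during which the pair is in range."""
        ivs = self.intervals.get(_ordered(a, b), [])
        if not ivs:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([np.arange(s, e, dtype=np.int64)
                               for s, e in ivs])

    def in_range_seconds(self, a: str, b: str) -> int:
        return sum(e - s for s, e in self.intervals.get(_ordered(a, b), []))

    def iter_samples(self) -> Iterator[Tuple[int, str, str]]:
        for (a, b), ivs in sorted(self.intervals.items()):
            for s, e in ivs:
                for sec in range(s, e):
                    yield sec, a, b

    def to_csv(self, path) -> None:
        """Diagnostic per-second export: columns second,tag_a,tag_b."""
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["second", "tag_a", "tag_b"])
            rows = sorted(self.iter_samples())
            w.writerows(rows)


def _bout_intervals(rng: np.random.Generator, window: Interval,
                    mean_on: float, mean_off: float) -> List[Interval]:
    """Alternating exponential off/on renewal process inside a window."""
    lo, hi = window
    out: List[Interval] = []
    t = lo
    # random phase: start mid-off on average
    t += rng.exponential(mean_off / 2.0)
    while t < hi:
        on = max(1.0, rng.exponential(mean_on))
        s = int(t)
        e = int(min(t + on, hi))
        if e > s:
            out.append((s, e))
        t += on + max(1.0, rng.exponential(mean_off))
    return out


def simulate_proximity(scenario: Scenario,
                       seed: Optional[int] = None) -> ProximityStream:
    """Generate the ground-truth proximity stream for a scenario.

    Deterministic for a fixed (scenario, seed); distinct seeds change bout
    placement only, never the schedule skeleton (turnout windows, fence-hook
    co-location, transits, off-shift bookkeeping storage).
    """
    if seed is None:
        seed = scenario.seed
    total = scenario.total_seconds()
    pairs: Dict[Pair, List[Interval]] = {}

    def add(a: str, b: str, ivs: Iterable[Interval]) -> None:
        if a == b:
            return
        pairs.setdefault(_ordered(a, b), []).extend(ivs)

    static_ids = {t.id for t in scenario.static_tags}
    ts, te = scenario.turnout_window

    for day in range(1, scenario.n_days + 1):
        d0 = (day - 1) * DAY_S
        t_start, t_end = d0 + ts, d0 + te
        overnight = [(d0, t_start), (t_end + scenario.transit_s, d0 + DAY_S)]

        # fence-hook clustering: halters of a pasture's horses hang together
        by_pasture: Dict[str, List[Horse]] = {}
        for h in scenario.horses:
            by_pasture.setdefault(scenario.pasture_of(h, day), []).append(h)
        for pasture, group in by_pasture.items():
            for ha, hb in itertools.combinations(group, 2):
                add(ha.id, hb.id, [(t_start, t_end)])
            if pasture in static_ids:
                for h in group:
                    add(h.id, pasture, [(t_start, t_end)])

        # transit to/from pasture: brief window at barn door + own aisle tag
        for h in scenario.horses:
            for t0 in (t_start - scenario.transit_s, t_end):
                iv = [(max(d0, t0), min(d0 + DAY_S, t0 + scenario.transit_s))]
                if "barn_door" in static_ids:
                    add(h.id, "barn_door", iv)
                if h.aisle in static_ids:
                    add(h.id, h.aisle, iv)

        # overnight stall-neighbour bouts (same aisle only)
        for ha, hb in itertools.combinations(scenario.horses, 2):
            if ha.aisle != hb.aisle:
                continue
            r = _rng(seed, "stall", day, ha.id, hb.id)
            for win in overnight:
                add(ha.id, hb.id,
                    _bout_intervals(r, win, scenario.stall_bout_mean_on_s,
                                    scenario.stall_bout_mean_off_s))

        # evening training/grooming bouts
        activities = [loc for loc in _ACTIVITY_LOCATIONS if loc in static_ids]
        for h in scenario.horses:
            r = _rng(seed, "training", day, h.id)
            n_bouts = r.poisson(scenario.training_bouts_per_day)
            for _ in range(n_bouts):
                evening = (t_end + scenario.transit_s, d0 + DAY_S)
                if evening[1] - evening[0] < 600:
                    continue
                dur = int(max(60, r.exponential(scenario.training_bout_mean_s)))
                s = int(r.integers(evening[0], max(evening[0] + 1,
                                                   evening[1] - dur)))
                e = min(s + dur, d0 + DAY_S)
                if activities:
                    loc = activities[int(r.integers(len(activities)))]
                    add(h.id, loc, [(s, e)])
                if scenario.people:
                    # handler is present only while on shift
                    p = scenario.people[int(r.integers(len(scenario.people)))]
                    on_shift = [(d0 + a, d0 + b) for a, b in p.shifts]
                    handled = [(max(s, lo), min(e, hi)) for lo, hi in on_shift
                               if min(e, hi) > max(s, lo)]
                    add(h.id, p.id, handled)

        # people: entry/exit transits with service locations during shifts,
        # bookkeeping storage off shift
        service = [loc for loc in ("tack_room", "feed_room", "pasture_1",
                                   "pasture_2", "pasture_3", "pasture_4")
                   if loc in static_ids]
        for p in scenario.people:
            r = _rng(seed, "person", day, p.id)
            shift_ivs = [(d0 + a, d0 + b) for a, b in p.shifts]
            for lo, hi in shift_ivs:
                n_visits = r.poisson(scenario.person_transits_per_shift)
                for _ in range(n_visits):
                    if not service or hi - lo <= 2 * scenario.transit_s:
                        continue
                    loc = service[int(r.integers(len(service)))]
                    s = int(r.integers(lo, hi - scenario.transit_s))
                    add(p.id, loc, [(s, s + scenario.transit_s)])
            # off-shift: tag stored with the bookkeeping tag
            off = _off_shift(shift_ivs, d0, d0 + DAY_S)
            add(p.id, scenario.bookkeeping_tag_id, off)

        # tags sitting together in storage also sense each other; these are
        # exactly the contacts the bookkeeping-vicinity rule later deletes
        for pa, pb in itertools.combinations(scenario.people, 2):
            off_a = _off_shift([(d0 + s, d0 + e) for s, e in pa.shifts],
                               d0, d0 + DAY_S)
            off_b = _off_shift([(d0 + s, d0 + e) for s, e in pb.shifts],
                               d0, d0 + DAY_S)
            add(pa.id, pb.id, _intersect(off_a, off_b))

    return ProximityStream(total_seconds=total, intervals=pairs)


def _intersect(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if e > s:
                out.append((s, e))
    return _merge_intervals(out)


def _off_shift(shift_ivs: Sequence[Interval], lo: int, hi: int) -> List[Interval]:
    """Complement of shift windows within [lo, hi)."""
    out = []
    cur = lo
    for s, e in sorted(shift_ivs):
        s, e = max(s, lo), min(e, hi)
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < hi:
        out.append((cur, hi))
    return out


def strip_bookkeeping(stream: ProximityStream,
                      bookkeeping_tag_id: str) -> ProximityStream:
    """Remove bookkeeping-vicinity proximity from a ground-truth stream.

    Drops every pair involving the bookkeeping tag, and for every other
    pair subtracts the seconds during which either participant was itself
    in range of the bookkeeping tag.  This is the truth-side counterpart of
    the cleaning pipeline's bookkeeping-removal stage, used when comparing
    pipeline output against ground truth.
    """
    vicinity: Dict[str, List[Interval]] = {}
    for (a, b), ivs in stream.intervals.items():
        if bookkeeping_tag_id in (a, b):
            other = b if a == bookkeeping_tag_id else a
            vicinity.setdefault(other, []).extend(ivs)
    out: Dict[Pair, List[Interval]] = {}
    for (a, b), ivs in stream.intervals.items():
        if bookkeeping_tag_id in (a, b):
            continue
        drop = _merge_intervals(vicinity.get(a, []) + vicinity.get(b, []))
        kept = _subtract(ivs, drop)
        if kept:
            out[(a, b)] = kept
    return ProximityStream(total_seconds=stream.total_seconds,
                           intervals=out)


def _subtract(ivs: Sequence[Interval],
              drop: Sequence[Interval]) -> List[Interval]:
    """Set-subtract merged interval list ``drop`` from interval list ``ivs``."""
    out: List[Interval] = []
    for s, e in _merge_intervals(ivs):
        cur = s
        for ds, de in drop:
            if de <= cur or ds >= e:
                continue
            if ds > cur:
                out.append((cur, ds))
            cur = max(cur, de)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


# ---------------------------------------------------------------------------
# Truth networks
# ---------------------------------------------------------------------------

@dataclass
class TruthNetworkSet:
    """Per-day undirected weighted edge lists derived directly from a
    ProximityStream; weight = in-range seconds / 3600.  Serves as the oracle
    for end-to-end recovery tests of the emulator + cleaning pipeline.
    """

    day_length_s: int
    #: day index (1-based) -> {ordered pair -> weight in hours}
    days: Dict[int, Dict[Pair, float]]

    def weight(self, day: int, a: str, b: str) -> float:
        return self.days.get(day, {}).get(_ordered(a, b), 0.0)

    def total_hours(self) -> float:
        return sum(w for d in self.days.values() for w in d.values())


def truth_networks(stream: ProximityStream,
                   day_length_s: int = DAY_S) -> TruthNetworkSet:
    """Bin a proximity stream into day-long truth edge lists by direct
    second counting (no washout merging, no sensing noise)."""
    if day_length_s <= 0:
        raise ValueError("day_length_s must be positive")
    n_days = max(1, -(-stream.total_seconds // day_length_s))
    days: Dict[int, Dict[Pair, float]] = {d: {} for d in range(1, n_days + 1)}
    for pair, ivs in stream.intervals.items():
        for s, e in ivs:
            d_first = s // day_length_s
            d_last = (e - 1) // day_length_s
            for d in range(d_first, d_last + 1):
                lo, hi = d * day_length_s, (d + 1) * day_length_s
                secs = min(e, hi) - max(s, lo)
                if secs > 0:
                    day = d + 1
                    days.setdefault(day, {})
                    days[day][pair] = days[day].get(pair, 0.0) + secs / 3600.0
    return TruthNetworkSet(day_length_s=day_length_s, days=days)
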