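"""Cleaning pipeline: raw tag logs to reconciled wall-clock contact events.

The stages mirror the post-processing a proximity-tag deployment needs
before any network can be built:

1. ``validate_ids`` -- drop records whose internal IDs do not resolve
   against the tag registry (aberrant data).
2. ``assemble_events`` -- fold each tag's BEGIN/ONGOING/END record stream
   into per-partner contact events on the tag's own clock, closing orphan
   sessions left open by battery death or restarts.
3. ``to_wall_clock`` -- shift tag-local times onto the wall clock using the
   recorded battery-insertion anchor of each tag.
4. ``filter_window`` -- keep only the study period, clipping events that
   straddle a boundary.
5. ``remove_bookkeeping`` -- delete contacts involving the bookkeeping tag
   and contacts made in its vicinity (i.e. while a participant was itself
   in contact with the bookkeeping tag).
6. ``reconcile_duplicates`` -- each physical contact is logged by both
   participants; collapse the two records into one using a configurable
   policy (single designated tag, mean of the two clocks, or the maximum
   recorded duration).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .facility_sim import Interval, Pair, _ordered
from .tag_emulator import ContactStatus, RawEventRecord, TagLog, TagParams

REJECT_UNREGISTERED = "unregistered_id"
REJECT_ORPHAN_END = "orphan_end"
REJECT_ORPHAN_ONGOING = "orphan_ongoing"

FLAG_ORPHAN_OPEN = "orphan_open"
FLAG_ONE_SIDED = "one_sided"
FLAG_CLIPPED = "clipped"


class RegistryError(ValueError):
    """Raised when the tag registry violates its invariants."""


@dataclass(frozen=True)
class RegistryEntry:
    external_id: str
    internal_id: int
    role: str  # horse | person | location | bookkeeping
    label: str = ""
    #: wall-clock second of the tag's battery insertion (clock anchor)
    anchor_s: Optional[int] = None


@dataclass
class TagRegistry:
    """One-to-one external/internal ID mapping with per-tag role and the
    battery-insertion anchor used to move tag-local times onto the wall
    clock."""

    entries: List[RegistryEntry]

    def __post_init__(self):
        ext = [e.external_id for e in self.entries]
        ints = [e.internal_id for e in self.entries]
        if len(set(ext)) != len(ext):
            raise RegistryError("duplicate external_id in registry")
        if len(set(ints)) != len(ints):
            raise RegistryError("duplicate internal_id in registry")
        self._by_internal = {e.internal_id: e for e in self.entries}
        self._by_external = {e.external_id: e for e in self.entries}

    @classmethod
    def from_params(cls, params: Mapping[str, TagParams],
                    roles: Mapping[str, str]) -> "TagRegistry":
        entries = [RegistryEntry(external_id=p.external_id or tid,
                                 internal_id=p.internal_id,
                                 role=roles.get(tid, "location"),
                                 label=tid,
                                 anchor_s=p.clock_offset_s)
                   for tid, p in sorted(params.items())]
        return cls(entries=entries)

    def by_internal(self, internal_id: int) -> Optional[RegistryEntry]:
        return self._by_internal.get(internal_id)

    def by_external(self, external_id: str) -> Optional[RegistryEntry]:
        return self._by_external.get(external_id)

    def bookkeeping_tag(self) -> RegistryEntry:
        bk = [e for e in self.entries if e.role == "bookkeeping"]
        if len(bk) != 1:
            raise RegistryError(
                f"registry must designate exactly one bookkeeping tag, "
                f"found {len(bk)}")
        return bk[0]

    def roles(self) -> Dict[str, str]:
        return {e.external_id: e.role for e in self.entries}

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["external_id", "internal_id", "role", "label",
                        "anchor_s"])
            for e in self.entries:
                w.writerow([e.external_id, e.internal_id, e.role, e.label,
                            "" if e.anchor_s is None else e.anchor_s])

    @classmethod
    def from_csv(cls, path) -> "TagRegistry":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                anchor = row.get("anchor_s", "")
                entries.append(RegistryEntry(
                    external_id=row["external_id"],
                    internal_id=int(row["internal_id"]),
                    role=row["role"],
                    label=row.get("label", ""),
                    anchor_s=int(anchor) if anchor not in ("", None) else None))
        return cls(entries=entries)


@dataclass(frozen=True)
class ContactEvent:
    """A reconciled interval contact between two tags on the wall clock.

    ``duration_s = end_wall_s - start_wall_s`` (a one-second contact has
    duration 0, matching firmware end-minus-start arithmetic).
    """

    tag_a: str
    tag_b: str
    start_wall_s: int
    end_wall_s: int
    provenance: str = ""
    flags: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.tag_a == self.tag_b:
            raise ValueError("self-contact event")
        if self.end_wall_s < self.start_wall_s:
            raise ValueError("event end precedes start")
        a, b = _ordered(self.tag_a, self.tag_b)
        object.__setattr__(self, "tag_a", a)
        object.__setattr__(self, "tag_b", b)

    @property
    def pair(self) -> Pair:
        return (self.tag_a, self.tag_b)

    @property
    def duration_s(self) -> int:
        return self.end_wall_s - self.start_wall_s


@dataclass(frozen=True)
class TagLocalEvent:
    """A folded contact session on a single tag's local clock."""

    source_internal_id: int
    partner_internal_id: int
    start_local_s: int
    end_local_s: int
    flags: Tuple[str, ...] = ()


@dataclass(frozen=True)
class RejectedRecord:
    record: RawEventRecord
    reason: str


# ---------------------------------------------------------------------------
# Stage 1: ID validation
# ---------------------------------------------------------------------------

def validate_ids(records: Iterable[RawEventRecord], registry: TagRegistry
                 ) -> Tuple[List[RawEventRecord], List[RejectedRecord]]:
    """Split records into those whose source and partner internal IDs both
    resolve against the registry, and rejected ones with a reason code."""
    clean: List[RawEventRecord] = []
    rejected: List[RejectedRecord] = []
    for rec in records:
        if (registry.by_internal(rec.source_internal_id) is None
                or registry.by_internal(rec.partner_internal_id) is None):
            rejected.append(RejectedRecord(rec, REJECT_UNREGISTERED))
        else:
            clean.append(rec)
    return clean, rejected


# ---------------------------------------------------------------------------
# Stage 2: session assembly (tag-local clock)
# ---------------------------------------------------------------------------

def assemble_events(records: Sequence[RawEventRecord]
                    ) -> Tuple[List[TagLocalEvent], List[RejectedRecord]]:
    """Fold one tag's record stream into per-partner contact events.

    Records must all share one source tag.  Sessions follow the
    BEGIN / ONGOING* / END grammar per partner; an orphan BEGIN (the tag
    died or restarted before writing END) is closed at the last ONGOING
    time (or its own time if none was seen) and flagged; an END or ONGOING
    with no open session is rejected.
    """
    events: List[TagLocalEvent] = []
    rejected: List[RejectedRecord] = []
    # open sessions: partner -> (begin_time, last_seen_time)
    open_sessions: Dict[int, Tuple[int, int]] = {}
    source_ids = {r.source_internal_id for r in records}
    if len(source_ids) > 1:
        raise ValueError(
            f"records from multiple source tags: {sorted(source_ids)}")

    def close(partner: int, flag: Optional[str] = None) -> None:
        begin, last = open_sessions.pop(partner)
        flags = (flag,) if flag else ()
        events.append(TagLocalEvent(
            source_internal_id=next(iter(source_ids)),
            partner_internal_id=partner,
            start_local_s=begin, end_local_s=last, flags=flags))

    for rec in records:
        partner = rec.partner_internal_id
        status = rec.status
        if status == ContactStatus.BEGIN:
            if partner in open_sessions:
                # a new BEGIN implies the previous session was cut short
                close(partner, FLAG_ORPHAN_OPEN)
            open_sessions[partner] = (rec.source_time_s, rec.source_time_s)
        elif status == ContactStatus.ONGOING:
            if partner not in open_sessions:
                rejected.append(RejectedRecord(rec, REJECT_ORPHAN_ONGOING))
            else:
                begin, _ = open_sessions[partner]
                open_sessions[partner] = (begin, rec.source_time_s)
        elif status == ContactStatus.END:
            if partner not in open_sessions:
                rejected.append(RejectedRecord(rec, REJECT_ORPHAN_END))
            else:
                begin, _ = open_sessions[partner]
                open_sessions[partner] = (begin, rec.source_time_s)
                close(partner)
        else:
            rejected.append(RejectedRecord(rec, f"unknown_status_{status}"))

    for partner in sorted(open_sessions):
        close(partner, FLAG_ORPHAN_OPEN)
    events.sort(key=lambda e: (e.start_local_s, e.partner_internal_id))
    return events, rejected


# ---------------------------------------------------------------------------
# Stage 3: wall clock
# ---------------------------------------------------------------------------

def to_wall_clock(events: Sequence[TagLocalEvent], registry: TagRegistry
                  ) -> List[ContactEvent]:
    """Shift tag-local events onto the wall clock using each source tag's
    battery-insertion anchor; resolves internal IDs to external IDs."""
    out: List[ContactEvent] = []
    for ev in events:
        src = registry.by_internal(ev.source_internal_id)
        part = registry.by_internal(ev.partner_internal_id)
        if src is None or part is None:
            raise RegistryError("event references unregistered internal id")
        if src.anchor_s is None:
            raise RegistryError(
                f"tag {src.external_id!r} has no battery-insertion anchor")
        out.append(ContactEvent(
            tag_a=src.external_id, tag_b=part.external_id,
            start_wall_s=ev.start_local_s + src.anchor_s,
            end_wall_s=ev.end_local_s + src.anchor_s,
            provenance=src.external_id, flags=ev.flags))
    return out


# ---------------------------------------------------------------------------
# Stage 4: study window
# ---------------------------------------------------------------------------

def filter_window(events: Sequence[ContactEvent], start_wall: int,
                  end_wall: int, clip: bool = True) -> List[ContactEvent]:
    """Keep events inside the study period [start_wall, end_wall).

    Events wholly outside are discarded.  Straddling events are clipped to
    the window with duration recomputed (set ``clip=False`` to drop them
    whole instead)."""
    if start_wall >= end_wall:
        raise ValueError("window start must precede end")
    out: List[ContactEvent] = []
    for ev in events:
        if ev.end_wall_s < start_wall or ev.start_wall_s >= end_wall:
            continue
        s = max(ev.start_wall_s, start_wall)
        e = min(ev.end_wall_s, end_wall - 1)
        if (s, e) == (ev.start_wall_s, ev.end_wall_s):
            out.append(ev)
        elif clip:
            flags = ev.flags if FLAG_CLIPPED in ev.flags else \
                ev.flags + (FLAG_CLIPPED,)
            out.append(replace(ev, start_wall_s=s, end_wall_s=e, flags=flags))
    return out


# ---------------------------------------------------------------------------
# Stage 5: bookkeeping-tag removal
# ---------------------------------------------------------------------------

def remove_bookkeeping(events: Sequence[ContactEvent], registry: TagRegistry,
                       slack_s: int = 0) -> List[ContactEvent]:
    """Delete contacts recorded in the vicinity of the bookkeeping tag.

    Removes every event involving the bookkeeping tag itself, and every
    event of a tag T that falls wholly inside an interval during which T
    was in contact with the bookkeeping tag (those are contacts between
    tags sitting together in storage, not real proximity).  ``slack_s``
    expands the bookkeeping intervals on both sides before the containment
    check to absorb clock jitter.
    """
    bk = registry.bookkeeping_tag().external_id
    vicinity: Dict[str, List[Interval]] = {}
    for ev in events:
        if bk in ev.pair:
            other = ev.tag_b if ev.tag_a == bk else ev.tag_a
            vicinity.setdefault(other, []).append(
                (ev.start_wall_s - slack_s, ev.end_wall_s + slack_s))

    def in_vicinity(tag: str, s: int, e: int) -> bool:
        return any(lo <= s and e <= hi for lo, hi in vicinity.get(tag, ()))

    out: List[ContactEvent] = []
    for ev in events:
        if bk in ev.pair:
            continue
        if (in_vicinity(ev.tag_a, ev.start_wall_s, ev.end_wall_s)
                or in_vicinity(ev.tag_b, ev.start_wall_s, ev.end_wall_s)):
            continue
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# Stage 6: duplicate reconciliation
# ---------------------------------------------------------------------------

RECONCILE_POLICIES = ("first_tag", "mean", "max")


def reconcile_duplicates(events: Sequence[ContactEvent],
                         tolerance_s: int = 300,
                         policy: str = "first_tag") -> List[ContactEvent]:
    """Collapse the two per-participant logs of each physical contact.

    For every unordered pair, events recorded by the two tags are matched
    greedily by start-time proximity (within ``tolerance_s``).  Matched
    pairs become one event with times chosen by ``policy``:

    * ``first_tag`` (default heuristic): keep the times recorded by the
      pair's lexicographically first tag;
    * ``mean``: average the two recorded start and end times;
    * ``max``: keep the recording with the larger duration.

    One-sided events (the partner restarted, died, or missed the contact)
    are retained as-is and flagged.
    """
    if policy not in RECONCILE_POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    by_pair: Dict[Pair, List[ContactEvent]] = {}
    for ev in events:
        by_pair.setdefault(ev.pair, []).append(ev)

    out: List[ContactEvent] = []
    for (a, b), evs in sorted(by_pair.items()):
        side_a = sorted((e for e in evs if e.provenance == a),
                        key=lambda e: e.start_wall_s)
        side_b = sorted((e for e in evs if e.provenance == b),
                        key=lambda e: e.start_wall_s)
        neither = [e for e in evs if e.provenance not in (a, b)]
        out.extend(neither)  # already-reconciled or external events

        used_b = [False] * len(side_b)
        j = 0
        for ea in side_a:
            match = None
            for k in range(j, len(side_b)):
                if used_b[k]:
                    continue
                dt = side_b[k].start_wall_s - ea.start_wall_s
                if dt > tolerance_s:
                    break
                if abs(dt) <= tolerance_s:
                    match = k
                    break
            if match is None:
                out.append(replace(ea, flags=ea.flags + (FLAG_ONE_SIDED,))
                           if FLAG_ONE_SIDED not in ea.flags else ea)
                continue
            eb = side_b[match]
            used_b[match] = True
            j = match
            out.append(_merge_pair(ea, eb, policy))
        for k, eb in enumerate(side_b):
            if not used_b[k]:
                out.append(replace(eb, flags=eb.flags + (FLAG_ONE_SIDED,))
                           if FLAG_ONE_SIDED not in eb.flags else eb)
    out.sort(key=lambda e: (e.start_wall_s, e.pair))
    return out


def _merge_pair(ea: ContactEvent, eb: ContactEvent,
                policy: str) -> ContactEvent:
    flags = tuple(sorted(set(ea.flags) | set(eb.flags)))
    if policy == "first_tag":
        chosen = ea if ea.provenance == ea.tag_a else eb
    elif policy == "max":
        chosen = ea if ea.duration_s >= eb.duration_s else eb
    else:  # mean
        s = (ea.start_wall_s + eb.start_wall_s) // 2
        e = (ea.end_wall_s + eb.end_wall_s) // 2
        return replace(ea, start_wall_s=s, end_wall_s=e,
                       provenance=f"{ea.provenance}+{eb.provenance}",
                       flags=flags)
    return replace(chosen, flags=flags)


# ---------------------------------------------------------------------------
# Convenience: full pipeline
# ---------------------------------------------------------------------------

def clean_events(logs: Mapping[str, TagLog], registry: TagRegistry,
                 window: Optional[Interval] = None,
                 drop_bookkeeping: bool = True,
                 tolerance_s: int = 300,
                 policy: str = "first_tag") -> List[ContactEvent]:
    """Run the full cleaning pipeline over a set of tag logs."""
    wall_events: List[ContactEvent] = []
    for tid in sorted(logs):
        recs, _ = validate_ids(logs[tid].records, registry)
        local, _ = assemble_events(recs)
        wall_events.extend(to_wall_clock(local, registry))
    if window is not None:
        wall_events = filter_window(wall_events, window[0], window[1])
    if drop_bookkeeping:
        wall_events = remove_bookkeeping(wall_events, registry)
    return reconcile_duplicates(wall_events, tolerance_s=tolerance_s,
                                policy=policy)


EVENT_COLUMNS = ("tag_a", "tag_b", "start_wall_s", "end_wall_s",
                 "duration_s", "flags")


def write_events_csv(events: Sequence[ContactEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for ev in events:
            w.writerow([ev.tag_a, ev.tag_b, ev.start_wall_s, ev.end_wall_s,
                        ev.duration_s, "|".join(ev.flags)])


def read_events_csv(path) -> List[ContactEvent]:
    out: List[ContactEvent] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            flags = tuple(f for f in row.get("flags", "").split("|") if f)
            out.append(ContactEvent(
                tag_a=row["tag_a"], tag_b=row["tag_b"],
                start_wall_s=int(row["start_wall_s"]),
                end_wall_s=int(row["end_wall_s"]), flags=flags))
    return out
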