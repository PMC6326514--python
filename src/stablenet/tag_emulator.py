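"""Emulation of battery-powered proximity-tag firmware.

Each tag is a 2.4 GHz active RFID badge with 8 MB of onboard flash, a 1 Hz
sense/record loop, and no real-time clock: time is a counter that starts at
battery insertion, so every tag runs on its own offset clock.  A contact
event with a partner opens at the first sensed second, stays open while the
partner keeps being sensed, and is terminated once the partner has been out
of range for a full washout period (default 30 s); the recorded end time is
the last sensed second.  Both participants log the event independently.
Each stored record costs 16 bytes, giving a capacity of 524,288 records on
an 8 MB part.

The emulator layers the firmware's imperfections on top of a ground-truth
:class:`~stablenet.facility_sim.ProximityStream`: per-second sensing misses,
sporadic restarts (during which a tag neither senses nor is sensible),
battery depletion, optional spurious detections of configured non-proximal
partners, and the one-partner-at-a-time recording limitation, which here
affects only the order in which same-second records land in flash.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .facility_sim import DAY_S, Interval, ProximityStream

#: flash size and record footprint of the stock hardware
FLASH_BYTES = 8 * 1024 * 1024
BYTES_PER_EVENT = 16
DEFAULT_WASHOUT_S = 30


class ContactStatus(enum.IntEnum):
    BEGIN = 1
    ONGOING = 2
    END = 3


class RawEventRecord(NamedTuple):
    """One 16-byte-equivalent flash record as written by the firmware."""

    trial_id: int
    source_internal_id: int
    partner_internal_id: int
    source_time_s: int   # tag-local seconds on the writing tag's clock
    partner_time_s: int  # the partner's clock reading for the same instant
    status: int          # ContactStatus value


class EmulatorConfigError(ValueError):
    """Raised when a stream tag has no parameters or parameters are invalid."""


def event_capacity(flash_bytes: int, bytes_per_event: int) -> int:
    """Number of records a flash part can hold: floor(flash / record size)."""
    if flash_bytes <= 0 or bytes_per_event <= 0:
        raise ValueError("flash_bytes and bytes_per_event must be positive")
    return flash_bytes // bytes_per_event


@dataclass(frozen=True)
class TagParams:
    """Per-tag hardware/firmware parameters.

    ``clock_offset_s`` is the wall-clock second of battery insertion, so
    tag-local time = wall time - offset.  ``battery_life_s`` counts from
    insertion.  ``p_miss`` is the per-second probability that a true
    in-range partner is not sensed; ``p_spurious`` the per-second
    probability of sensing each tag in ``spurious_candidates`` while not in
    range (emulating wall-to-wall radio anomalies).
    """

    tag_id: str
    internal_id: int
    external_id: str = ""
    clock_offset_s: int = 0
    battery_life_s: int = 10 * 365 * DAY_S
    restart_rate_per_day: float = 0.0
    restart_gap_s: int = 1
    p_miss: float = 0.0
    p_spurious: float = 0.0
    spurious_candidates: Tuple[str, ...] = ()
    memory_capacity_events: int = event_capacity(FLASH_BYTES, BYTES_PER_EVENT)
    washout_s: int = DEFAULT_WASHOUT_S
    ongoing_interval_s: int = 60

    def __post_init__(self):
        if not (0 <= self.internal_id < 2 ** 32):
            raise EmulatorConfigError("internal_id must fit 32-bit unsigned")
        if not (0.0 <= self.p_miss <= 1.0 and 0.0 <= self.p_spurious <= 1.0):
            raise EmulatorConfigError("probabilities must lie in [0, 1]")
        if self.memory_capacity_events <= 0:
            raise EmulatorConfigError("memory capacity must be positive")
        if self.washout_s < 1:
            raise EmulatorConfigError("washout_s must be >= 1")
        if self.clock_offset_s < 0 or self.battery_life_s < 0:
            raise EmulatorConfigError("offset and battery life must be >= 0")
        if self.restart_rate_per_day < 0 or self.restart_gap_s < 1:
            raise EmulatorConfigError("invalid restart parameters")


@dataclass
class TagLog:
    """The full flash contents of one tag after the deployment."""

    tag_id: str
    records: List[RawEventRecord] = field(default_factory=list)
    truncated: bool = False

    @property
    def events_stored(self) -> int:
        return len(self.records)

    def last_activity_local_s(self) -> Optional[int]:
        if not self.records:
            return None
        return max(r.source_time_s for r in self.records)


def _stable_int(*keys) -> int:
    h = 0
    for k in keys:
        h = zlib.crc32(repr(k).encode(), h)
    return h & 0x7FFF_FFFF


def _rng(seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFF_FFFF, _stable_int(*keys)])


def default_tag_params(tag_ids: Sequence[str], seed: int = 0,
                       ideal: bool = False,
                       **overrides) -> Dict[str, TagParams]:
    """Generate a parameter set emulating a realistic field deployment.

    Defaults model the observed behaviour of the hardware: battery insertion
    staggered over the first 5 minutes of deployment (clock offsets
    Uniform{0..300} s), coin-cell lives clustered a little past six days with
    a ~1-in-8 chance of early depletion, occasional sporadic restarts with a
    short recovery gap, and a small per-second sensing miss probability.
    With ``ideal=True`` all imperfections are switched off (zero offsets,
    effectively infinite battery, no restarts, no misses) -- the
    configuration used for recovery tests against ground truth.

    ``overrides`` are applied to every tag's parameters.
    """
    params: Dict[str, TagParams] = {}
    for i, tid in enumerate(sorted(tag_ids)):
        internal = 0x1000 + i
        if ideal:
            kw = dict(clock_offset_s=0, restart_rate_per_day=0.0,
                      p_miss=0.0, p_spurious=0.0)
        else:
            r = _rng(seed, "params", tid)
            if r.random() < 0.12:
                battery = int(r.uniform(2.0, 5.0) * DAY_S)
            else:
                battery = int(np.clip(r.normal(6.2, 0.3), 5.1, 8.0) * DAY_S)
            kw = dict(clock_offset_s=int(r.integers(0, 301)),
                      battery_life_s=battery,
                      restart_rate_per_day=0.2,
                      restart_gap_s=5,
                      p_miss=0.02)
        kw.update(overrides)
        params[tid] = TagParams(tag_id=tid, internal_id=internal,
                                external_id=tid, **kw)
    return params


# ---------------------------------------------------------------------------
# Emulation
# ---------------------------------------------------------------------------

def _down_windows(p: TagParams, seed: int,
                  total_seconds: int) -> List[Interval]:
    """Wall-clock windows during which the tag is not operating: before
    battery insertion, after depletion, and during restart gaps."""
    down: List[Interval] = []
    if p.clock_offset_s > 0:
        down.append((0, p.clock_offset_s))
    power_end = p.clock_offset_s + p.battery_life_s
    if power_end < total_seconds:
        down.append((power_end, total_seconds))
    if p.restart_rate_per_day > 0:
        active = max(0, min(total_seconds, power_end) - p.clock_offset_s)
        r = _rng(seed, "restarts", p.tag_id)
        n = r.poisson(p.restart_rate_per_day * active / DAY_S)
        for t in sorted(r.integers(p.clock_offset_s,
                                   p.clock_offset_s + max(1, active),
                                   size=n)):
            down.append((int(t), int(t) + p.restart_gap_s))
    return down


def _alive_mask(seconds: np.ndarray, down: Sequence[Interval],
                total_seconds: int) -> np.ndarray:
    mask = np.ones(seconds.size, dtype=bool)
    for s, e in down:
        mask &= ~((seconds >= s) & (seconds < min(e, total_seconds)))
    return mask


def _segment(sensed: np.ndarray, washout_s: int) -> List[Interval]:
    """Washout segmentation of a sorted array of sensed seconds.

    A session terminates when the partner goes unsensed for at least
    ``washout_s`` consecutive seconds; the session end is the last sensed
    second (closed interval (start_second, end_second))."""
    if sensed.size == 0:
        return []
    gaps = np.diff(sensed) - 1  # unsensed seconds between consecutive senses
    cut = np.nonzero(gaps >= washout_s)[0]
    starts = np.concatenate(([0], cut + 1))
    ends = np.concatenate((cut, [sensed.size - 1]))
    return [(int(sensed[i]), int(sensed[j])) for i, j in zip(starts, ends)]


def emulate(stream: ProximityStream, params: Mapping[str, TagParams],
            seed: int = 0, trial_id: int = 1) -> Dict[str, TagLog]:
    """Run the firmware emulation for every tag against a proximity stream.

    Returns one :class:`TagLog` per tag in ``params`` (tags present in the
    parameter set but absent from the stream produce empty logs).  Both
    participants of a physical contact record it independently on their own
    clocks; records are written in emission order (BEGIN at the opening
    second, ONGOING on a fixed cadence, END once the washout has elapsed),
    with same-second records ordered by a seeded random shuffle emulating
    the one-partner-at-a-time recording loop.  Once a tag's flash is full it
    stops recording (but keeps transmitting); once its battery dies it stops
    doing anything.
    """
    stream_tags = set(stream.tags)
    missing = stream_tags - set(params)
    if missing:
        raise EmulatorConfigError(
            f"no TagParams for stream tags: {sorted(missing)}")

    total = stream.total_seconds
    down = {tid: _down_windows(p, seed, total) for tid, p in params.items()}

    # sensed seconds per (observer, partner), observer's own clock not yet
    # applied (wall seconds)
    sensed: Dict[Tuple[str, str], List[np.ndarray]] = {}

    for a, b in stream.pairs:
        secs = stream.pair_seconds(a, b)
        both = (_alive_mask(secs, down[a], total)
                & _alive_mask(secs, down[b], total))
        secs = secs[both]
        if secs.size == 0:
            continue
        for obs, part in ((a, b), (b, a)):
            p_miss = params[obs].p_miss
            if p_miss > 0.0:
                r = _rng(seed, "miss", obs, part)
                keep = r.random(secs.size) >= p_miss
                got = secs[keep]
            else:
                got = secs
            if got.size:
                sensed.setdefault((obs, part), []).append(got)

    # spurious detections: one-sided, only of configured candidates
    for tid, p in params.items():
        if p.p_spurious <= 0.0 or not p.spurious_candidates:
            continue
        r = _rng(seed, "spurious", tid)
        alive = np.arange(total, dtype=np.int64)
        alive = alive[_alive_mask(alive, down[tid], total)]
        for cand in p.spurious_candidates:
            hits = alive[r.random(alive.size) < p.p_spurious]
            if hits.size:
                sensed.setdefault((tid, cand), []).append(hits)

    logs = {tid: TagLog(tag_id=tid) for tid in params}
    pending: Dict[str, List[Tuple[int, float, RawEventRecord]]] = {
        tid: [] for tid in params}

    for (obs, part), chunks in sensed.items():
        if part not in params:
            raise EmulatorConfigError(f"no TagParams for partner {part!r}")
        po, pp = params[obs], params[part]
        secs = np.unique(np.concatenate(chunks))
        r_tie = _rng(seed, "order", obs, part)
        for start, end in _segment(secs, po.washout_s):
            def rec(wall: int, status: ContactStatus) -> RawEventRecord:
                return RawEventRecord(
                    trial_id=trial_id,
                    source_internal_id=po.internal_id,
                    partner_internal_id=pp.internal_id,
                    source_time_s=wall - po.clock_offset_s,
                    partner_time_s=wall - pp.clock_offset_s,
                    status=int(status))

            emit = pending[obs]
            emit.append((start, r_tie.random(), rec(start,
                                                    ContactStatus.BEGIN)))
            t = start + po.ongoing_interval_s
            while t <= end:
                emit.append((t, r_tie.random(),
                             rec(t, ContactStatus.ONGOING)))
                t += po.ongoing_interval_s
            # END is written once the washout has elapsed; a tag that dies
            # first leaves the session open in flash (orphan BEGIN)
            end_emit = end + po.washout_s
            if end_emit < po.clock_offset_s + po.battery_life_s:
                emit.append((end_emit, r_tie.random(),
                             rec(end, ContactStatus.END)))

    for tid, emit in pending.items():
        emit.sort(key=lambda t: (t[0], t[1]))
        cap = params[tid].memory_capacity_events
        log = logs[tid]
        if len(emit) > cap:
            log.truncated = True
            emit = emit[:cap]
        log.records = [r for _, _, r in emit]
    return logs


# ---------------------------------------------------------------------------
# Summaries and interchange
# ---------------------------------------------------------------------------

def battery_survival_summary(logs: Iterable[TagLog],
                             threshold_s: int) -> Tuple[int, int, float]:
    """Count tags whose last recorded activity reached ``threshold_s``
    (tag-local seconds); returns (n_survived, n_total, percent) with the
    percentage rounded to one decimal."""
    logs = list(logs)
    if not logs:
        raise ValueError("no tag logs supplied")
    n_total = len(logs)
    n_survived = 0
    for log in logs:
        last = log.last_activity_local_s()
        if last is not None and last >= threshold_s:
            n_survived += 1
    percent = round(100.0 * n_survived / n_total, 1)
    return n_survived, n_total, percent


RAW_LOG_COLUMNS = ("trial_id", "source_internal_id", "partner_internal_id",
                   "source_time_s", "partner_time_s", "status")


def write_tag_logs(logs: Mapping[str, TagLog], directory,
                   combined_name: str = "all_tags.csv") -> None:
    """Export one raw-log CSV per tag plus a combined CSV (the interchange
    format consumed by the cleaning pipeline)."""
    import csv
    import os

    os.makedirs(directory, exist_ok=True)
    all_rows: List[RawEventRecord] = []
    for tid in sorted(logs):
        log = logs[tid]
        with open(os.path.join(directory, f"{tid}.csv"), "w",
                  newline="") as fh:
            w = csv.writer(fh)
            w.writerow(RAW_LOG_COLUMNS)
            w.writerows(log.records)
        all_rows.extend(log.records)
    with open(os.path.join(directory, combined_name), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RAW_LOG_COLUMNS)
        w.writerows(all_rows)


def read_tag_log_csv(path) -> List[RawEventRecord]:
    import csv

    out: List[RawEventRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(RawEventRecord(
                trial_id=int(row["trial_id"]),
                source_internal_id=int(row["source_internal_id"]),
                partner_internal_id=int(row["partner_internal_id"]),
                source_time_s=int(row["source_time_s"]),
                partner_time_s=int(row["partner_time_s"]),
                status=int(row["status"])))
    return out
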