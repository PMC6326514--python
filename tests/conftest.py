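"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from typing import Dict, List, Sequence, Tuple

import pytest

import stablenet as sn


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive; never reuse package code)
# ---------------------------------------------------------------------------

def washout_segment_oracle(seconds: Sequence[int],
                           washout_s: int) -> List[Tuple[int, int]]:
    """Single-pass brute-force washout segmentation of sensed seconds:
    a session ends once >= washout_s consecutive seconds go unsensed; the
    recorded end is the last sensed second."""
    out: List[Tuple[int, int]] = []
    seconds = sorted(set(int(s) for s in seconds))
    start = prev = None
    for s in seconds:
        if prev is None:
            start = prev = s
            continue
        if s - prev - 1 >= washout_s:
            out.append((start, prev))
            start = s
        prev = s
    if prev is not None:
        out.append((start, prev))
    return out


def washout_merge_intervals(intervals: Sequence[Tuple[int, int]],
                            washout_s: int) -> List[Tuple[int, int]]:
    """Merge half-open in-range intervals whose separating gap is shorter
    than the washout; returns closed (first_second, last_second) spans."""
    merged: List[List[int]] = []
    for s, e in sorted(intervals):
        if merged and s - merged[-1][1] < washout_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e - 1) for s, e in merged]


def classify_oracle(gold_edges, test_edges, nodes):
    """Exhaustive unordered-pair enumeration of the confusion counts."""
    norm = lambda p: tuple(sorted(p))
    gold = {norm(p) for p in gold_edges}
    test = {norm(p) for p in test_edges}
    tp = fp = tn = fn = 0
    for pair in itertools.combinations(sorted(nodes), 2):
        g, t = pair in gold, pair in test
        tp += g and t
        fp += t and not g
        fn += g and not t
        tn += not g and not t
    return tp, fp, tn, fn


def truth_weights_by_day(stream: sn.ProximityStream,
                         day_s: int = 86400) -> Dict[int, Dict[tuple, float]]:
    """Direct second-counting day-binned weights from a proximity stream."""
    out: Dict[int, Dict[tuple, float]] = {}
    for sec, a, b in stream.iter_samples():
        d = sec // day_s + 1
        out.setdefault(d, {})
        out[d][(a, b)] = out[d].get((a, b), 0.0) + 1 / 3600.0
    return out


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_scenario_2d() -> sn.Scenario:
    return sn.default_scenario(n_days=2)


@pytest.fixture(scope="session")
def ideal_run(default_scenario_2d) -> sn.StudyRun:
    """A 2-day default-facility deployment with ideal tags (no offsets,
    misses, or restarts) -- the recovery-test workhorse."""
    return sn.run_study(default_scenario_2d, seed=11, ideal=True)


@pytest.fixture(scope="session")
def noisy_run(default_scenario_2d) -> sn.StudyRun:
    """Same deployment with realistic tag imperfections."""
    return sn.run_study(default_scenario_2d, seed=11, ideal=False)


@pytest.fixture(scope="session")
def confined_scenario() -> sn.Scenario:
    """A horses-only 7-day scenario whose horse-horse contacts are confined
    within pasture/aisle survey groups (no weekend move)."""
    base = sn.default_scenario(n_days=7, weekend_move=False)
    return sn.Scenario(horses=base.horses, people=(), static_tags=(),
                       n_days=7)


@pytest.fixture(scope="session")
def day1_network() -> sn.DailyNetwork:
    return sn.day1_horse_network()
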