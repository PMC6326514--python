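"""End-to-end convenience: scenario -> tag logs -> events -> networks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

from . import facility_sim, ingest_clean, networks, tag_emulator
from .facility_sim import ProximityStream, Scenario, TruthNetworkSet
from .ingest_clean import ContactEvent, TagRegistry
from .networks import DailyNetwork
from .tag_emulator import TagLog, TagParams


@dataclass
class StudyRun:
    """All intermediate products of one simulated deployment."""

    scenario: Scenario
    stream: ProximityStream
    params: Dict[str, TagParams]
    registry: TagRegistry
    logs: Dict[str, TagLog]
    events: List[ContactEvent]
    daily: List[DailyNetwork]
    truth: TruthNetworkSet


def run_study(scenario: Scenario, seed: int = 0, ideal: bool = False,
              tag_overrides: Optional[Mapping] = None,
              reconcile_policy: str = "first_tag") -> StudyRun:
    """Simulate a deployment and run the full processing pipeline.

    ``ideal=True`` switches off every tag imperfection (used for recovery
    tests against the simulator's ground truth); ``tag_overrides`` are
    forwarded to :func:`stablenet.tag_emulator.default_tag_params`.
    """
    stream = facility_sim.simulate_proximity(scenario, seed=seed)
    params = tag_emulator.default_tag_params(
        scenario.tag_ids, seed=seed, ideal=ideal, **(tag_overrides or {}))
    registry = TagRegistry.from_params(params, scenario.roles())
    logs = tag_emulator.emulate(stream, params, seed=seed)
    events = ingest_clean.clean_events(
        logs, registry, window=(0, scenario.total_seconds()),
        policy=reconcile_policy)
    daily = networks.aggregate_daily(
        events, n_days=scenario.n_days, node_kinds=scenario.roles())
    truth = facility_sim.truth_networks(stream)
    return StudyRun(scenario=scenario, stream=stream, params=params,
                    registry=registry, logs=logs, events=events,
                    daily=daily, truth=truth)
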