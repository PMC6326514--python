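"""Cleaning pipeline: ID validation, session folding, clocks, windows,
bookkeeping removal, duplicate reconciliation, and end-to-end recovery."""

import pytest

import stablenet as sn
from stablenet.ingest_clean import (FLAG_ONE_SIDED, FLAG_ORPHAN_OPEN,
                                    REJECT_ORPHAN_END, REJECT_UNREGISTERED,
                                    RegistryEntry, RegistryError,
                                    read_events_csv, write_events_csv)
from stablenet.tag_emulator import ContactStatus, RawEventRecord

from conftest import washout_merge_intervals


def rec(src, part, t, status, t_part=None):
    return RawEventRecord(1, src, part, t, t if t_part is None else t_part,
                          int(status))


@pytest.fixture
def registry():
    return sn.TagRegistry(entries=[
        RegistryEntry("h1", 1, "horse", anchor_s=0),
        RegistryEntry("h2", 2, "horse", anchor_s=100),
        RegistryEntry("p3", 3, "person", anchor_s=0),
        RegistryEntry("p4", 4, "person", anchor_s=0),
        RegistryEntry("bk", 9, "bookkeeping", anchor_s=0),
    ])


class TestRegistry:
    def test_duplicate_internal_id_rejected(self):
        with pytest.raises(RegistryError):
            sn.TagRegistry(entries=[RegistryEntry("a", 1, "horse"),
                                    RegistryEntry("b", 1, "horse")])

    def test_round_trip_csv(self, registry, tmp_path):
        path = tmp_path / "registry.csv"
        registry.to_csv(path)
        back = sn.TagRegistry.from_csv(path)
        assert back.entries == registry.entries

    def test_exactly_one_bookkeeping_tag(self, registry):
        assert registry.bookkeeping_tag().external_id == "bk"
        no_bk = sn.TagRegistry(entries=[RegistryEntry("a", 1, "horse")])
        with pytest.raises(RegistryError):
            no_bk.bookkeeping_tag()


class TestValidateIds:
    def test_unknown_partner_rejected(self, registry):
        records = [rec(1, 2, 0, ContactStatus.BEGIN),
                   rec(1, 77, 5, ContactStatus.BEGIN)]
        clean, rejected = sn.validate_ids(records, registry)
        assert len(clean) == 1
        assert rejected[0].reason == REJECT_UNREGISTERED
        assert rejected[0].record.partner_internal_id == 77

    def test_all_known_no_rejections(self, registry):
        records = [rec(1, 2, 0, ContactStatus.BEGIN),
                   rec(2, 1, 0, ContactStatus.BEGIN)]
        clean, rejected = sn.validate_ids(records, registry)
        assert rejected == [] and len(clean) == 2


class TestAssembleEvents:
    def test_begin_ongoing_end(self):
        records = [rec(1, 2, 10, ContactStatus.BEGIN),
                   rec(1, 2, 70, ContactStatus.ONGOING),
                   rec(1, 2, 130, ContactStatus.END)]
        events, rejected = sn.assemble_events(records)
        assert rejected == []
        (ev,) = events
        assert (ev.start_local_s, ev.end_local_s) == (10, 130)
        assert ev.end_local_s - ev.start_local_s == 120

    def test_orphan_begin_closed_degenerate(self):
        events, _ = sn.assemble_events([rec(1, 2, 10, ContactStatus.BEGIN)])
        (ev,) = events
        assert (ev.start_local_s, ev.end_local_s) == (10, 10)
        assert FLAG_ORPHAN_OPEN in ev.flags

    def test_orphan_begin_closed_at_last_ongoing(self):
        records = [rec(1, 2, 10, ContactStatus.BEGIN),
                   rec(1, 2, 70, ContactStatus.ONGOING),
                   rec(1, 2, 130, ContactStatus.ONGOING)]
        (ev,), _ = sn.assemble_events(records)
        assert ev.end_local_s == 130
        assert FLAG_ORPHAN_OPEN in ev.flags

    def test_end_without_begin_rejected(self):
        events, rejected = sn.assemble_events(
            [rec(1, 2, 50, ContactStatus.END)])
        assert events == []
        assert rejected[0].reason == REJECT_ORPHAN_END

    def test_interleaved_partners(self):
        """Sessions with two partners interleaved in one log fold into two
        correct events (oracle replay by hand)."""
        records = [rec(1, 2, 0, ContactStatus.BEGIN),
                   rec(1, 3, 5, ContactStatus.BEGIN),
                   rec(1, 2, 60, ContactStatus.ONGOING),
                   rec(1, 3, 65, ContactStatus.ONGOING),
                   rec(1, 3, 80, ContactStatus.END),
                   rec(1, 2, 90, ContactStatus.END)]
        events, rejected = sn.assemble_events(records)
        assert rejected == []
        spans = {(e.partner_internal_id, e.start_local_s, e.end_local_s)
                 for e in events}
        assert spans == {(2, 0, 90), (3, 5, 80)}


class TestToWallClock:
    def test_anchor_shift(self, registry):
        events, _ = sn.assemble_events([rec(2, 1, 50, ContactStatus.BEGIN),
                                        rec(2, 1, 80, ContactStatus.END)])
        (wall,) = sn.to_wall_clock(events, registry)
        assert (wall.start_wall_s, wall.end_wall_s) == (150, 180)
        assert wall.provenance == "h2"

    def test_zero_anchor_identity(self, registry):
        events, _ = sn.assemble_events([rec(1, 2, 50, ContactStatus.BEGIN),
                                        rec(1, 2, 80, ContactStatus.END)])
        (wall,) = sn.to_wall_clock(events, registry)
        assert (wall.start_wall_s, wall.end_wall_s) == (50, 80)

    def test_missing_anchor_errors(self):
        reg = sn.TagRegistry(entries=[RegistryEntry("a", 1, "horse"),
                                      RegistryEntry("b", 2, "horse")])
        events, _ = sn.assemble_events([rec(1, 2, 0, ContactStatus.BEGIN),
                                        rec(1, 2, 9, ContactStatus.END)])
        with pytest.raises(RegistryError, match="anchor"):
            sn.to_wall_clock(events, reg)

    def test_dual_recording_anchors_agree(self):
        """Two tags recording one physical contact map to wall-clock starts
        within the insertion-window bound once anchors are applied."""
        stream = sn.ProximityStream(total_seconds=5000,
                                    intervals={("a", "b"): [(1000, 1400)]})
        params = sn.default_tag_params(("a", "b"), ideal=True)
        params["a"] = sn.TagParams(tag_id="a", internal_id=1,
                                   clock_offset_s=250)
        params["b"] = sn.TagParams(tag_id="b", internal_id=2,
                                   clock_offset_s=10)
        logs = sn.emulate(stream, params, seed=0)
        reg = sn.TagRegistry.from_params(params, {"a": "horse",
                                                  "b": "horse"})
        walls = []
        for tid in ("a", "b"):
            local, _ = sn.assemble_events(logs[tid].records)
            walls.extend(sn.to_wall_clock(local, reg))
        starts = [w.start_wall_s for w in walls]
        assert max(starts) - min(starts) == 0  # exact anchors cancel offsets


class TestFilterWindow:
    def _ev(self, s, e):
        return sn.ContactEvent(tag_a="a", tag_b="b", start_wall_s=s,
                               end_wall_s=e)

    def test_outside_dropped_inside_kept(self):
        evs = [self._ev(0, 50), self._ev(200, 300)]
        out = sn.filter_window(evs, 100, 1000)
        assert out == [evs[1]]

    def test_straddle_clipped(self):
        (ev,) = sn.filter_window([self._ev(900, 1100)], 100, 1001)
        assert ev.end_wall_s == 1000
        assert ev.duration_s == 100

    def test_idempotent(self):
        evs = [self._ev(0, 500), self._ev(400, 1500), self._ev(1600, 1700)]
        once = sn.filter_window(evs, 100, 1000)
        twice = sn.filter_window(once, 100, 1000)
        assert once == twice

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            sn.filter_window([], 10, 10)


class TestRemoveBookkeeping:
    def _ev(self, a, b, s, e):
        return sn.ContactEvent(tag_a=a, tag_b=b, start_wall_s=s,
                               end_wall_s=e)

    def test_direct_bookkeeping_contact_removed(self, registry):
        evs = [self._ev("bk", "p3", 0, 100), self._ev("h1", "h2", 0, 100)]
        out = sn.remove_bookkeeping(evs, registry)
        assert out == [evs[1]]

    def test_vicinity_contact_removed(self, registry):
        evs = [self._ev("bk", "p3", 0, 1000),
               self._ev("p3", "p4", 100, 900)]
        assert sn.remove_bookkeeping(evs, registry) == []

    def test_contact_outside_vicinity_retained(self, registry):
        evs = [self._ev("bk", "p3", 0, 100),
               self._ev("p3", "p4", 500, 900),
               self._ev("h1", "h2", 0, 50)]
        out = sn.remove_bookkeeping(evs, registry)
        assert set(out) == set(evs[1:])

    def test_idempotent(self, registry):
        evs = [self._ev("bk", "p3", 0, 1000),
               self._ev("p3", "p4", 100, 900),
               self._ev("h1", "h2", 2000, 2100)]
        once = sn.remove_bookkeeping(evs, registry)
        assert sn.remove_bookkeeping(once, registry) == once

    def test_no_bookkeeping_tag_is_config_error(self):
        reg = sn.TagRegistry(entries=[RegistryEntry("a", 1, "horse")])
        with pytest.raises(RegistryError):
            sn.remove_bookkeeping([], reg)


class TestReconcileDuplicates:
    def _pair_events(self, s1, e1, s2, e2):
        ea = sn.ContactEvent(tag_a="a", tag_b="b", start_wall_s=s1,
                             end_wall_s=e1, provenance="a")
        eb = sn.ContactEvent(tag_a="a", tag_b="b", start_wall_s=s2,
                             end_wall_s=e2, provenance="b")
        return ea, eb

    def test_identical_events_collapse(self):
        ea, eb = self._pair_events(100, 200, 100, 200)
        (out,) = sn.reconcile_duplicates([ea, eb])
        assert (out.start_wall_s, out.end_wall_s) == (100, 200)

    def test_mean_policy_averages(self):
        ea, eb = self._pair_events(100, 200, 103, 206)
        (out,) = sn.reconcile_duplicates([ea, eb], policy="mean")
        assert (out.start_wall_s, out.end_wall_s) == (101, 203)

    def test_first_tag_policy_keeps_first_tags_times(self):
        ea, eb = self._pair_events(100, 200, 103, 206)
        (out,) = sn.reconcile_duplicates([ea, eb], policy="first_tag")
        assert (out.start_wall_s, out.end_wall_s) == (100, 200)

    def test_max_policy_keeps_longer_duration(self):
        ea, eb = self._pair_events(100, 200, 103, 250)
        (out,) = sn.reconcile_duplicates([ea, eb], policy="max")
        assert (out.start_wall_s, out.end_wall_s) == (103, 250)

    def test_one_sided_event_flagged(self):
        """A partner restart produces a one-sided record that survives
        reconciliation with a flag."""
        stream = sn.ProximityStream(total_seconds=4000,
                                    intervals={("a", "b"): [(100, 600)]})
        params = sn.default_tag_params(("a", "b"), ideal=True)
        # partner 'b' has a tiny battery: only 'a' records a usable event
        params["b"] = sn.TagParams(tag_id="b", internal_id=2,
                                   battery_life_s=150)
        logs = sn.emulate(stream, params, seed=0)
        reg = sn.TagRegistry.from_params(params, {"a": "horse",
                                                  "b": "horse"})
        events = []
        for tid in ("a", "b"):
            local, _ = sn.assemble_events(logs[tid].records)
            events.extend(sn.to_wall_clock(local, reg))
        out = sn.reconcile_duplicates(events)
        sided = [e for e in out if FLAG_ONE_SIDED in e.flags]
        # b died mid-contact: its orphan fragment and a's later re-opened
        # session cannot both match
        assert sided or len(out) == 1

    def test_far_apart_events_not_matched(self):
        ea, eb = self._pair_events(0, 100, 1000, 1100)
        out = sn.reconcile_duplicates([ea, eb], tolerance_s=300)
        assert len(out) == 2
        assert all(FLAG_ONE_SIDED in e.flags for e in out)

    def test_conservation_total_duration_never_increases(self, noisy_run):
        """Reconciliation never increases total event hours."""
        # recompute the pre-reconciliation totals from the raw logs
        events = []
        for tid in sorted(noisy_run.logs):
            recs, _ = sn.validate_ids(noisy_run.logs[tid].records,
                                      noisy_run.registry)
            local, _ = sn.assemble_events(recs)
            events.extend(sn.to_wall_clock(local, noisy_run.registry))
        before = sum(e.duration_s for e in events)
        after = sum(e.duration_s
                    for e in sn.reconcile_duplicates(events))
        assert after <= before

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            sn.reconcile_duplicates([], policy="median")


class TestEventsCsv:
    def test_round_trip(self, tmp_path):
        evs = [sn.ContactEvent("a", "b", 0, 100, flags=("clipped",)),
               sn.ContactEvent("a", "c", 50, 60)]
        path = tmp_path / "events.csv"
        write_events_csv(evs, path)
        back = read_events_csv(path)
        assert [(e.pair, e.start_wall_s, e.end_wall_s, e.flags)
                for e in back] == \
            [(e.pair, e.start_wall_s, e.end_wall_s, e.flags) for e in evs]


class TestEndToEndRecovery:
    def test_ideal_pipeline_recovers_truth(self, ideal_run):
        """With ideal tags, reconciled events reproduce the simulator's
        truth bouts merged under the 30 s washout rule, to within 1 s per
        event (firmware duration is end-minus-start of sensed seconds)."""
        sc = ideal_run.scenario
        stripped = sn.strip_bookkeeping(ideal_run.stream,
                                        sc.bookkeeping_tag_id)
        expected = {}
        for pair, ivs in stripped.intervals.items():
            for s, e in washout_merge_intervals(ivs, 30):
                expected.setdefault(pair, []).append((s, e))
        got = {}
        for ev in ideal_run.events:
            got.setdefault(ev.pair, []).append(
                (ev.start_wall_s, ev.end_wall_s))
        assert set(got) == set(expected)
        for pair in expected:
            assert sorted(got[pair]) == sorted(expected[pair])

    def test_daily_weights_match_truth_within_tolerance(self, ideal_run):
        sc = ideal_run.scenario
        stripped = sn.strip_bookkeeping(ideal_run.stream,
                                        sc.bookkeeping_tag_id)
        day_s = 86400
        expected = {}
        n_events = {}
        for pair, ivs in stripped.intervals.items():
            for s, e in washout_merge_intervals(ivs, 30):
                d = s // day_s + 1
                expected[(d, pair)] = expected.get((d, pair), 0.0) \
                    + (e - s) / 3600.0
                n_events[(d, pair)] = n_events.get((d, pair), 0) + 1
        for net in ideal_run.daily:
            for a, b, w in net.graph.edges(data="weight_hours"):
                key = (net.day_index, tuple(sorted((a, b))))
                tol = (n_events.get(key, 1) + 1) / 3600.0
                assert w == pytest.approx(expected.get(key, 0.0), abs=tol)
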