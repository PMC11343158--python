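"""Walk coordination: assignment, arbitration, release rule, log pairing."""

import pytest

from patchwalk.scheduler import (
    CellSite,
    ExperimentLog,
    LogIntegrityError,
    ProtocolError,
    QueueExhausted,
    Retire,
    SchedulerConfig,
    StartAttempt,
    StartClean,
    StartScreen,
    WalkCoordinator,
    pairs_from_log,
    select_next_cell,
)

HOMES = {"a": (0.0, 0.0, 50.0), "b": (250.0, 0.0, 50.0)}


class TestSelectNextCell:
    def test_nearest_cell_wins(self):
        q = [CellSite(1, (60.0, 0, 0)), CellSite(2, (30.0, 0, 0))]
        assert select_next_cell((0, 0, 0), q).id == 2

    def test_tie_breaks_to_lowest_id(self):
        q = [CellSite(5, (50.0, 0, 0)), CellSite(2, (0.0, 50.0, 0))]
        assert select_next_cell((0, 0, 0), q).id == 2

    def test_selected_cell_leaves_queue_and_is_assigned(self):
        q = [CellSite(1, (10.0, 0, 0))]
        c = select_next_cell((0, 0, 0), q)
        assert c.status == "assigned" and q == []

    def test_empty_queue_signals_exhaustion(self):
        with pytest.raises(QueueExhausted):
            select_next_cell((0, 0, 0), [])

    def test_collision_radius_skips_nearby_candidates(self):
        q = [CellSite(1, (10.0, 0, 0)), CellSite(2, (100.0, 0, 0))]
        c = select_next_cell((0, 0, 0), q, avoid=(12.0, 0, 0), collision_radius=20.0)
        assert c.id == 2


def drive_all_success(coordinator, screen_outcomes=("not_connected", "not_connected")):
    """Drive a coordinator to completion with every attempt succeeding.

    Durations: hunt 1, seal+break-in 2, clean 1, screen 1 time units —
    processed in deterministic FIFO order.
    """
    t = 0.0
    pending = list(coordinator.start(t))
    while pending:
        act = pending.pop(0)
        t += 1.0
        if isinstance(act, StartAttempt):
            pending += coordinator.advance("hunt_done", act.pipette, t)
            t += 1.0
            pending += coordinator.advance("attempt_succeeded", act.pipette, t)
        elif isinstance(act, StartClean):
            pending += coordinator.advance("clean_done", act.pipette, t)
        elif isinstance(act, StartScreen):
            pending += coordinator.advance(
                "screen_done",
                None,
                t,
                outcome_ab=screen_outcomes[0],
                outcome_ba=screen_outcomes[1],
            )
        elif isinstance(act, Retire):
            pass
    return coordinator


class TestWalkCoordinator:
    def test_all_success_walk_chains_n_minus_1_pairs(self, line_cells):
        cells = line_cells[:4]
        coord = drive_all_success(WalkCoordinator(cells, HOMES))
        chained = [(p.cell_a, p.cell_b) for p in coord.pairs]
        assert len(coord.pairs) == 3
        # each consecutive pair shares exactly one held cell: a chain
        for prev, nxt in zip(coord.pairs, coord.pairs[1:]):
            assert len({prev.cell_a, prev.cell_b} & {nxt.cell_a, nxt.cell_b}) == 1
        pairs, probed = pairs_from_log(coord.log)
        assert len(pairs) == 3 and probed == 6

    def test_release_rule_frees_earliest_whole_cell(self, line_cells):
        coord = drive_all_success(WalkCoordinator(line_cells[:3], HOMES))
        # after the first screen the pipette holding longest is released
        release_events = [e for e in coord.log.events if e.kind == "release"]
        first_wc = [e for e in coord.log.events if e.kind == "whole_cell"][0]
        assert release_events[0].pipette == first_wc.pipette

    def test_stage_mutual_exclusion(self, line_cells):
        coord = WalkCoordinator(line_cells[:4], HOMES)
        actions = coord.start(0.0)
        # both pipettes want to hunt; exactly one receives the stage
        assert sum(isinstance(a, StartAttempt) for a in actions) == 1
        owner = next(a.pipette for a in actions if isinstance(a, StartAttempt))
        # the other pipette's attempt begins only once the stage is released
        follow = coord.advance("hunt_done", owner, 1.0)
        assert any(
            isinstance(a, StartAttempt) and a.pipette != owner for a in follow
        )

    def test_failures_consume_cells_and_route_to_cleaning(self, line_cells):
        coord = WalkCoordinator(line_cells[:2], HOMES)
        actions = coord.start(0.0)
        pid = actions[0].pipette
        coord.advance("hunt_done", pid, 1.0)
        out = coord.advance("attempt_failed", pid, 2.0)
        assert any(isinstance(a, StartClean) for a in out)
        failed = [c for c in coord.log.cells.values() if c.status == "failed"]
        assert len(failed) == 1

    def test_queue_exhaustion_retires_pipette(self, line_cells):
        coord = WalkCoordinator(line_cells[:2], HOMES)
        actions = coord.start(0.0)
        pid = actions[0].pipette
        coord.advance("hunt_done", pid, 1.0)
        coord.advance("attempt_failed", pid, 2.0)
        out = coord.advance("clean_done", pid, 3.0)
        assert out == [Retire(pid)]
        with pytest.raises(ProtocolError):
            coord.advance("clean_done", pid, 4.0)

    def test_every_cell_ends_in_one_terminal_status(self, line_cells):
        coord = drive_all_success(WalkCoordinator(line_cells, HOMES))
        coord.finish(99.0)
        statuses = {c.id: c.status for c in coord.log.cells.values()}
        assert set(statuses.values()) <= {"released", "failed", "excluded"}

    def test_hold_expiry_releases_lonely_holder(self, line_cells):
        coord = WalkCoordinator(line_cells[:2], HOMES)
        actions = coord.start(0.0)
        pid = actions[0].pipette
        coord.advance("hunt_done", pid, 1.0)
        coord.advance("attempt_succeeded", pid, 2.0)
        out = coord.advance("hold_expired", pid, 47.0)
        assert any(isinstance(a, StartClean) for a in out)
        assert coord.pipettes[pid].held_cell is None


class TestPairsFromLog:
    def make_log(self, holds, cells=None):
        """holds: list of (pipette, cell, t_start, t_end)."""
        log = ExperimentLog(cells)
        events = []
        for pid, cid, t0, t1 in holds:
            events.append((t0, pid, cid, "whole_cell"))
            events.append((t1, pid, cid, "release"))
        for t, pid, cid, kind in sorted(events):
            log.append(t, pid, cid, kind)
        return log

    def test_empty_log_has_no_pairs(self):
        pairs, probed = pairs_from_log(ExperimentLog())
        assert pairs == [] and probed == 0

    def test_walk_log_over_seven_cells_yields_six_pairs(self):
        # pipettes alternate holds; six maximal co-held intervals
        holds = []
        for k in range(7):
            pid = "a" if k % 2 == 0 else "b"
            holds.append((pid, k + 1, 10.0 * k, 10.0 * k + 15.0))
        log = self.make_log(holds)
        pairs, probed = pairs_from_log(log)
        assert len(pairs) == 6 and probed == 12
        assert all(p.probes[0].outcome == "untested" for p in pairs)

    def test_many_pair_intervals_double_as_probed_count(self):
        holds = []
        t = 0.0
        for k in range(29):
            holds.append(("a", 2 * k + 1, t, t + 5.0))
            holds.append(("b", 2 * k + 2, t + 1.0, t + 4.0))
            t += 10.0
        pairs, probed = pairs_from_log(self.make_log(holds))
        assert len(pairs) == 29 and probed == 58

    def test_screen_outcomes_attach_to_their_interval(self):
        log = self.make_log([("a", 1, 0.0, 10.0), ("b", 2, 2.0, 12.0)])
        log.append(5.0, None, None, "screen_done",
                   cell_a=1, cell_b=2, outcome_ab="connected", outcome_ba="not_connected")
        log.events.sort(key=lambda e: e.t)
        pairs, _ = pairs_from_log(log)
        outcomes = {(p.pre, p.post): p.outcome for p in pairs[0].probes}
        assert outcomes == {(1, 2): "connected", (2, 1): "not_connected"}

    def test_contradictory_holds_raise(self):
        log = ExperimentLog()
        log.append(0.0, "a", 1, "whole_cell")
        log.append(1.0, "a", 2, "whole_cell")
        with pytest.raises(LogIntegrityError):
            pairs_from_log(log)

    def test_same_cell_coheld_is_an_integrity_error(self):
        log = self.make_log([("a", 1, 0.0, 10.0), ("b", 1, 2.0, 8.0)])
        with pytest.raises(LogIntegrityError):
            pairs_from_log(log)
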