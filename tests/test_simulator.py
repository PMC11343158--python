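"""Monte Carlo experiment simulation: reproducibility and closed-form limits."""

import numpy as np
import pytest

from patchwalk.simulator import (
    DurationSpec,
    SimulationConfig,
    StageDurations,
    compare_strategies,
    simulate_experiment,
    summarize_log,
)
from patchwalk.scheduler import ExperimentLog, pairs_from_log
from patchwalk.yield_model import (
    patchwalk_possible_connections,
    traditional_possible_connections,
)


def cfg(**kw):
    return SimulationConfig(**{"n_cells": 9, **kw})


class TestSimulateExperiment:
    def test_seed_reproducibility_bit_identical(self):
        a = simulate_experiment(cfg(), seed=42)
        b = simulate_experiment(cfg(), seed=42)
        assert [(e.t, e.pipette, e.cell, e.kind, e.payload) for e in a.events] == [
            (e.t, e.pipette, e.cell, e.kind, e.payload) for e in b.events
        ]
        c = simulate_experiment(cfg(), seed=43)
        assert [(e.t, e.kind) for e in c.events] != [(e.t, e.kind) for e in a.events]

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError):
            simulate_experiment(cfg())

    @pytest.mark.parametrize("n", [4, 10, 25])
    def test_all_success_walk_equals_closed_form(self, n):
        log = simulate_experiment(cfg(n_cells=n, success_prob=1.0), seed=5)
        s = summarize_log(log)
        assert s.pairs == n - 1
        assert s.probed_connections == 2 * (n - 1)
        assert s.probed_connections == patchwalk_possible_connections(n, 2)

    def test_all_success_traditional_equals_closed_form(self):
        log = simulate_experiment(
            cfg(n_cells=10, success_prob=1.0, strategy="traditional"), seed=5
        )
        s = summarize_log(log)
        assert s.pairs == 5
        assert s.probed_connections == traditional_possible_connections(10, 2)

    def test_zero_success_yields_no_pairs(self):
        s = summarize_log(simulate_experiment(cfg(success_prob=0.0), seed=9))
        assert s.whole_cells == 0 and s.pairs == 0
        assert s.attempts == 9  # every cell consumed by a failed attempt

    def test_probed_is_twice_pairs_and_bounded(self):
        for seed in range(5):
            s = summarize_log(simulate_experiment(cfg(), seed=seed))
            assert s.probed_connections == 2 * s.pairs
            assert s.pairs <= patchwalk_possible_connections(9, 2) // 2

    def test_stochastic_pairs_do_not_exceed_deterministic(self):
        det = summarize_log(simulate_experiment(cfg(success_prob=1.0), seed=3)).pairs
        for seed in range(5):
            sto = summarize_log(simulate_experiment(cfg(success_prob=0.5), seed=seed)).pairs
            assert sto <= det

    def test_attempt_tally_identity(self):
        s = summarize_log(simulate_experiment(cfg(), seed=17))
        assert s.attempts == s.whole_cells + s.failures

    def test_hold_limit_releases_lonely_holder(self):
        # one pipette succeeds but its partner always fails: the hold must
        # end at the limit, not block the run forever
        config = cfg(n_cells=4, success_prob=0.5, hold_limit_min=10.0)
        log = simulate_experiment(config, seed=1)
        holds = [e for e in log.events if e.kind == "whole_cell"]
        releases = [e for e in log.events if e.kind == "release"]
        assert len(releases) == len(holds)

    def test_stage_mutual_exclusion_throughout(self):
        log = simulate_experiment(cfg(n_cells=12), seed=21)
        hunting = set()
        for e in log.events:
            if e.kind == "attempt_start":
                assert not hunting, f"stage conflict at t={e.t}"
                hunting.add(e.pipette)
            elif e.kind == "hunt_done":
                hunting.discard(e.pipette)

    def test_walk_screens_follow_distance_model_support(self):
        log = simulate_experiment(cfg(n_cells=9), seed=2)
        for e in log.events:
            if e.kind == "screen_done":
                assert 0 < e.payload["distance_um"] < 400.0


class TestSummaries:
    def test_success_rate_printed_to_one_decimal(self):
        log = ExperimentLog()
        t = 0.0
        for k in range(18):
            log.append(t, "a", k + 1, "attempt_start")
            t += 1.0
            if k < 8:
                log.append(t, "a", k + 1, "whole_cell")
                t += 1.0
                log.append(t, "a", k + 1, "release")
            else:
                log.append(t, "a", k + 1, "attempt_failed")
            t += 1.0
        s = summarize_log(log)
        assert s.success_rate_pct == 44.4

    def test_empty_log_summarizes_to_zeros(self):
        s = summarize_log(ExperimentLog())
        assert s.attempts == 0 and s.pairs == 0 and s.success_rate_pct == 0.0

    def test_malformed_log_rejected(self):
        log = ExperimentLog()
        log.append(0.0, "a", 1, "attempt_start")
        with pytest.raises(ValueError):
            summarize_log(log)


class TestCompareStrategies:
    def test_deterministic_regime_matches_analytic_improvement(self):
        summary = compare_strategies(cfg(n_cells=10, success_prob=1.0), n_reps=2, seed=7)
        assert summary.mean_probed == {"patchwalk": 18.0, "traditional": 10.0}
        assert summary.improvement_fraction == pytest.approx(0.8)

    def test_stochastic_walk_still_dominates_on_average(self):
        summary = compare_strategies(cfg(n_cells=9), n_reps=8, seed=31)
        assert summary.mean_probed["patchwalk"] >= summary.mean_probed["traditional"]
        assert (summary.replicates.groupby("strategy").size() == 8).all()


def test_emergent_time_to_pair_is_order_ten_minutes():
    """Default stage durations put the time between paired recordings in
    the regime a two-pipette rig operates in (roughly 5-25 min)."""
    ttps = []
    for seed in range(6):
        s = summarize_log(simulate_experiment(cfg(n_cells=9), seed=seed))
        ttps += s.time_to_pair_min
    assert 5.0 < np.mean(ttps) < 25.0


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_cells=5, success_prob=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_cells=1, n_pipettes=2)
    with pytest.raises(ValueError):
        SimulationConfig(n_cells=9, strategy="diagonal")
    with pytest.raises(ValueError):
        DurationSpec(-1.0, 0.5)
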