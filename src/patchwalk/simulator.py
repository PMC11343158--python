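"""Seeded Monte Carlo simulation of full connection-screening experiments.

An experiment draws a synthetic cell map, then runs either strategy:

* **patchwalk** — the :class:`~patchwalk.scheduler.WalkCoordinator` control
  flow, driven by a small next-event loop (heap of timestamped completions).
* **traditional** — pipettes patch a group of ``p`` cells concurrently
  (each retrying with cleaning until whole cell), all ordered pairs in the
  group are screened, all pipettes retract, and the cycle repeats until the
  queue is exhausted.

Attempt outcomes are Bernoulli draws at the configured whole-cell success
probability (default 0.522, the empirical two-pipette rate). Stage
durations are gamma-distributed (positive support, mean/SD parameterized).
Each directed connection within a screened pair is drawn Bernoulli at the
distance-dependent connection probability for the pair's intersomatic
distance. Runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .connectivity_model import DistanceDecayModel, default_model
from .fixtures import CellMapSpec, default_home_positions, generate_cell_map
from .scheduler import (
    CellSite,
    ExperimentLog,
    Retire,
    SchedulerConfig,
    StartAttempt,
    StartClean,
    StartScreen,
    WalkCoordinator,
    euclidean,
    pairs_from_log,
    select_next_cell,
    QueueExhausted,
)

__all__ = [
    "DurationSpec",
    "StageDurations",
    "SimulationConfig",
    "LogSummary",
    "StrategySummary",
    "simulate_experiment",
    "summarize_log",
    "compare_strategies",
]


@dataclass(frozen=True)
class DurationSpec:
    """Gamma-distributed stage duration with a given mean and SD (minutes)."""

    mean_min: float
    sd_min: float

    def __post_init__(self) -> None:
        if self.mean_min <= 0 or self.sd_min < 0:
            raise ValueError("durations need positive mean and non-negative SD")

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd_min == 0:
            return self.mean_min
        shape = (self.mean_min / self.sd_min) ** 2
        scale = self.sd_min**2 / self.mean_min
        return float(rng.gamma(shape, scale))


@dataclass(frozen=True)
class StageDurations:
    """Per-stage duration distributions (minutes).

    Defaults are chosen so the emergent time between paired recordings in a
    walk is of order ten minutes, the regime a two-pipette rig operates in.
    """

    hunt: DurationSpec = DurationSpec(3.0, 1.5)
    gigaseal: DurationSpec = DurationSpec(2.5, 1.5)
    break_in: DurationSpec = DurationSpec(0.5, 0.2)
    clean: DurationSpec = DurationSpec(1.5, 0.5)
    screen: DurationSpec = DurationSpec(2.0, 0.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated experiment."""

    n_cells: int = 9
    n_pipettes: int = 2
    strategy: Literal["patchwalk", "traditional"] = "patchwalk"
    success_prob: float = 0.522
    durations: StageDurations = StageDurations()
    hold_limit_min: float = 45.0
    connectivity: Optional[DistanceDecayModel] = None
    cell_map: Optional[CellMapSpec] = None
    collision_radius_um: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.success_prob <= 1.0:
            raise ValueError("success_prob must lie in [0, 1]")
        if self.n_pipettes < 2:
            raise ValueError("need at least two pipettes")
        if self.strategy not in ("patchwalk", "traditional"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "patchwalk" and self.n_pipettes != 2:
            raise ValueError("the patch-walking coordinator drives two pipettes")
        if self.n_cells < self.n_pipettes:
            raise ValueError("need at least as many cells as pipettes")
        if self.hold_limit_min <= 0:
            raise ValueError("hold limit must be positive")

    @property
    def model(self) -> DistanceDecayModel:
        return self.connectivity or default_model()

    @property
    def map_spec(self) -> CellMapSpec:
        return self.cell_map or CellMapSpec(n_cells=self.n_cells)


def _resolve_rng(config: SimulationConfig, seed) -> np.random.Generator:
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is mandatory for stochastic simulation runs")
    return np.random.default_rng(seed)


def simulate_experiment(
    config: SimulationConfig,
    seed=None,
    cells: Optional[Sequence[CellSite]] = None,
    homes: Optional[dict] = None,
) -> ExperimentLog:
    """Run one seeded experiment and return its event log.

    ``seed`` (int or :class:`numpy.random.SeedSequence`) overrides
    ``config.seed``; one of the two must be given. A pre-built cell map
    (and optionally pipette homes) may be supplied instead of generating
    one from the config's map spec.
    """
    rng = _resolve_rng(config, seed)
    spec = replace(config.map_spec, n_cells=config.n_cells)
    if cells is None:
        cells = generate_cell_map(spec, rng=rng)
    if config.strategy == "patchwalk":
        return _simulate_walk(config, cells, spec, rng, homes)
    return _simulate_traditional(config, cells, spec, rng, homes)


# -- patch-walking event loop --------------------------------------------------


def _simulate_walk(
    config: SimulationConfig,
    cells: Sequence[CellSite],
    spec: CellMapSpec,
    rng: np.random.Generator,
    homes: Optional[dict] = None,
) -> ExperimentLog:
    coord = WalkCoordinator(
        cells,
        homes or default_home_positions(spec),
        SchedulerConfig(
            hold_limit_min=config.hold_limit_min,
            collision_radius_um=config.collision_radius_um,
        ),
    )
    d = config.durations
    heap: list[tuple[float, int, str, Optional[str], dict]] = []
    seq = 0

    def push(t: float, kind: str, pipette: Optional[str], **payload) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, seq, kind, pipette, payload))
        seq += 1

    def execute(actions, t: float) -> None:
        for act in actions:
            if isinstance(act, StartAttempt):
                push(t + d.hunt.draw(rng), "hunt_done", act.pipette)
            elif isinstance(act, StartClean):
                push(t + d.clean.draw(rng), "clean_done", act.pipette)
            elif isinstance(act, StartScreen):
                ca = coord.log.cells[act.cell_a]
                cb = coord.log.cells[act.cell_b]
                dist = euclidean(ca.position, cb.position)
                q = config.model.probability(dist)
                ab = "connected" if rng.random() < q else "not_connected"
                ba = "connected" if rng.random() < q else "not_connected"
                push(
                    t + d.screen.draw(rng),
                    "screen_done",
                    None,
                    outcome_ab=ab,
                    outcome_ba=ba,
                )
            elif isinstance(act, Retire):
                pass  # nothing to schedule

    execute(coord.start(0.0), 0.0)
    t = 0.0
    while heap:
        t, _, kind, pipette, payload = heapq.heappop(heap)
        if kind == "hunt_done":
            actions = coord.advance("hunt_done", pipette, t)
            execute(actions, t)
            success = rng.random() < config.success_prob
            dur = d.gigaseal.draw(rng) + d.break_in.draw(rng)
            push(t + dur, "attempt_succeeded" if success else "attempt_failed", pipette)
        elif kind == "attempt_succeeded":
            execute(coord.advance("attempt_succeeded", pipette, t), t)
            push(t + config.hold_limit_min, "hold_expired", pipette)
        elif kind in ("attempt_failed", "clean_done", "hold_expired"):
            pip = coord.pipettes[pipette]
            if kind == "hold_expired" and (
                pip.stage != "whole_cell"
                or pip.whole_cell_since is None
                or t - pip.whole_cell_since < config.hold_limit_min - 1e-9
            ):
                continue  # stale timer
            if pip.stage == "retracted":
                continue
            execute(coord.advance(kind, pipette, t), t)
        elif kind == "screen_done":
            execute(coord.advance("screen_done", None, t, **payload), t)
    coord.finish(t)
    return coord.log


# -- traditional multi-patch rounds -------------------------------------------


def _traditional_homes(p: int, spec: CellMapSpec) -> dict[str, tuple[float, float, float]]:
    lo, hi = spec.depth_band_um
    mid = (lo + hi) / 2.0
    y = spec.field_y_um / 2.0
    xs = np.linspace(0.0, spec.field_x_um, p)
    return {
        chr(ord("a") + i): (float(x), y, mid) for i, x in enumerate(xs)
    }


def _simulate_traditional(
    config: SimulationConfig,
    cells: Sequence[CellSite],
    spec: CellMapSpec,
    rng: np.random.Generator,
    homes: Optional[dict] = None,
) -> ExperimentLog:
    d = config.durations
    homes = homes or _traditional_homes(config.n_pipettes, spec)
    log = ExperimentLog(cells)
    queue = sorted(cells, key=lambda c: c.id)
    t_pipette = {pid: 0.0 for pid in homes}
    stage_free = 0.0
    active = set(homes)
    while len(active) >= 2 and queue:
        holders: dict[str, tuple[int, float]] = {}  # pid -> (cell, whole_cell time)
        for pid in sorted(active):
            # retry with cleaning until whole cell or queue exhausted
            while True:
                try:
                    cell = select_next_cell(homes[pid], queue)
                except QueueExhausted:
                    break
                t0 = max(t_pipette[pid], stage_free)
                log.append(t0, pid, cell.id, "attempt_start")
                t_hunt = t0 + d.hunt.draw(rng)
                stage_free = t_hunt  # hunting owns the stage/camera
                log.append(t_hunt, pid, cell.id, "hunt_done")
                t_done = t_hunt + d.gigaseal.draw(rng) + d.break_in.draw(rng)
                if rng.random() < config.success_prob:
                    cell.status = "whole_cell"
                    log.append(t_done, pid, cell.id, "whole_cell")
                    holders[pid] = (cell.id, t_done)
                    t_pipette[pid] = t_done
                    break
                cell.status = "failed"
                log.append(t_done, pid, cell.id, "attempt_failed")
                log.append(t_done, pid, None, "clean_start")
                t_clean = t_done + d.clean.draw(rng)
                log.append(t_clean, pid, None, "clean_done")
                t_pipette[pid] = t_clean
            if pid not in holders:
                active.discard(pid)
                log.append(t_pipette[pid], pid, None, "retire")
        if len(holders) >= 2:
            t_screen = max(tm for _, tm in holders.values())
            pids = sorted(holders)
            for i, pa in enumerate(pids):
                for pb in pids[i + 1 :]:
                    ca, cb = holders[pa][0], holders[pb][0]
                    dist = euclidean(log.cells[ca].position, log.cells[cb].position)
                    q = config.model.probability(dist)
                    ab = "connected" if rng.random() < q else "not_connected"
                    ba = "connected" if rng.random() < q else "not_connected"
                    log.append(t_screen, None, None, "screen_start", cell_a=ca, cell_b=cb)
                    t_screen += d.screen.draw(rng)
                    log.append(
                        t_screen, None, None, "screen_done",
                        cell_a=ca, cell_b=cb, outcome_ab=ab, outcome_ba=ba,
                        distance_um=dist,
                    )
        else:
            t_screen = max(
                [tm for _, tm in holders.values()], default=max(t_pipette.values())
            )
        # retract every holder, clean, next round
        for pid, (cid, _) in sorted(holders.items()):
            log.cells[cid].status = "released"
            log.append(t_screen, pid, cid, "release")
            log.append(t_screen, pid, None, "clean_start")
            t_clean = t_screen + d.clean.draw(rng)
            log.append(t_clean, pid, None, "clean_done")
            t_pipette[pid] = t_clean
    for pid in sorted(active):
        log.append(max(t_pipette.values()), pid, None, "retire")
    return log


# -- summaries -----------------------------------------------------------------


@dataclass
class LogSummary:
    """Tallies of one experiment log."""

    attempts: int
    whole_cells: int
    failures: int
    success_rate_pct: float
    pairs: int
    probed_connections: int
    found_connections: int
    total_time_min: float
    time_to_pair_min: list[float] = field(default_factory=list)
    attempt_duration_min: list[float] = field(default_factory=list)


def summarize_log(log: ExperimentLog) -> LogSummary:
    """Aggregate an event log into the standard experiment tallies."""
    attempts = log.count("attempt_start")
    whole = log.count("whole_cell")
    failures = log.count("attempt_failed")
    if attempts != whole + failures:
        raise ValueError(
            f"malformed log: {attempts} attempts but {whole} whole cells + {failures} failures"
        )
    pairs, probed = pairs_from_log(log)
    found = sum(
        (e.payload.get("outcome_ab") == "connected")
        + (e.payload.get("outcome_ba") == "connected")
        for e in log.events
        if e.kind == "screen_done"
    )
    rate = round(100.0 * whole / attempts, 1) if attempts else 0.0
    pair_starts = [e.t for e in log.events if e.kind == "screen_start"]
    ttp = list(np.diff([0.0] + pair_starts)) if pair_starts else []
    starts: dict[tuple[str, int], float] = {}
    durs: list[float] = []
    for e in log.events:
        if e.kind == "attempt_start":
            starts[(e.pipette, e.cell)] = e.t
        elif e.kind in ("whole_cell", "attempt_failed") and (e.pipette, e.cell) in starts:
            durs.append(e.t - starts.pop((e.pipette, e.cell)))
    return LogSummary(
        attempts=attempts,
        whole_cells=whole,
        failures=failures,
        success_rate_pct=rate,
        pairs=len(pairs),
        probed_connections=probed,
        found_connections=found,
        total_time_min=log.end_time,
        time_to_pair_min=[float(x) for x in ttp],
        attempt_duration_min=durs,
    )


@dataclass
class StrategySummary:
    """Paired-replicate comparison of the two strategies."""

    replicates: pd.DataFrame
    mean_probed: dict[str, float]
    improvement_fraction: float


def compare_strategies(config: SimulationConfig, n_reps: int = 10, seed=None) -> StrategySummary:
    """Run paired-seed replicates of both strategies and compare yields.

    Each replicate uses one seed for both strategies, so they see the same
    cell map and the same stream of stochastic draws.
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    base = seed if seed is not None else config.seed
    if base is None:
        raise ValueError("a seed is mandatory for stochastic simulation runs")
    rows = []
    for rep in range(n_reps):
        for strategy in ("traditional", "patchwalk"):
            cfg = replace(config, strategy=strategy, n_pipettes=2)
            log = simulate_experiment(cfg, seed=np.random.SeedSequence((base, rep)))
            s = summarize_log(log)
            rows.append(
                {
                    "rep": rep,
                    "strategy": strategy,
                    "attempts": s.attempts,
                    "whole_cells": s.whole_cells,
                    "pairs": s.pairs,
                    "probed_connections": s.probed_connections,
                    "found_connections": s.found_connections,
                    "total_time_min": s.total_time_min,
                }
            )
    df = pd.DataFrame(rows)
    means = df.groupby("strategy")["probed_connections"].mean().to_dict()
    trad = means.get("traditional", 0.0)
    improvement = means["patchwalk"] / trad - 1.0 if trad else float("nan")
    return StrategySummary(replicates=df, mean_probed=means, improvement_fraction=improvement)
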