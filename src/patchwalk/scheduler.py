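"""Patch-walking coordination: cell queue, assignment, and the walk rule.

The walk proceeds with two pipettes. Each pipette is assigned the queued
cell nearest its home position. A pipette that fails an attempt is cleaned
and assigned the next nearest cell. While one pipette holds a whole-cell
recording, the other keeps attempting; the moment both hold, the pair is
screened for connectivity in both directions. After the screen, the
pipette that achieved whole cell *first* is released, cleaned, and walked
on to a new cell — so the chain of paired recordings slides across the
tissue one cell at a time.

Stage/camera arbitration: hunting requires the microscope stage, so at most
one pipette hunts at a time; the other defers until the stage is released.

The :class:`WalkCoordinator` encodes this control flow as a pure state
machine: the caller (simulator or a scripted test) feeds it timestamped
completion events and executes the actions it returns. All decisions are
deterministic; ties in cell distance break toward the lowest cell id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

__all__ = [
    "CellSite",
    "PipetteAgent",
    "DirectedProbe",
    "PairedRecording",
    "Event",
    "ExperimentLog",
    "QueueExhausted",
    "LogIntegrityError",
    "ProtocolError",
    "StartAttempt",
    "StartClean",
    "StartScreen",
    "Retire",
    "WalkCoordinator",
    "SchedulerConfig",
    "euclidean",
    "select_next_cell",
    "pairs_from_log",
]

CellStatus = Literal["queued", "assigned", "whole_cell", "failed", "released", "excluded"]
PipetteStage = Literal[
    "idle", "moving", "hunting", "sealing", "breaking_in", "whole_cell", "cleaning", "retracted"
]
ProbeOutcome = Literal["connected", "not_connected", "untested"]


class QueueExhausted(Exception):
    """No queued cells remain for assignment; the pipette retires."""


class LogIntegrityError(Exception):
    """Event log contains contradictory or overlapping hold records."""


class ProtocolError(Exception):
    """An event referenced a pipette that cannot legally receive it."""


@dataclass
class CellSite:
    """A selectable neuron target: id, 3-D position (um), lifecycle status."""

    id: int
    position: tuple[float, float, float]
    status: CellStatus = "queued"


@dataclass
class PipetteAgent:
    """One pipette: home position, coarse stage, held cell, hold start time."""

    id: str
    home_position: tuple[float, float, float]
    stage: PipetteStage = "idle"
    held_cell: Optional[int] = None
    whole_cell_since: Optional[float] = None


@dataclass
class DirectedProbe:
    pre: int
    post: int
    outcome: ProbeOutcome = "untested"


@dataclass
class PairedRecording:
    """Interval during which two pipettes simultaneously hold whole-cell
    recordings; owns the two directed probed connections."""

    cell_a: int
    cell_b: int
    start: float
    end: float
    intersomatic_distance: float
    probes: tuple[DirectedProbe, DirectedProbe] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cell_a == self.cell_b:
            raise ValueError("a paired recording needs two distinct cells")
        if self.end < self.start:
            raise ValueError("pair interval must have end >= start")
        if self.probes is None:
            self.probes = (
                DirectedProbe(self.cell_a, self.cell_b),
                DirectedProbe(self.cell_b, self.cell_a),
            )


@dataclass(frozen=True)
class Event:
    """One timestamped log record (time in minutes)."""

    t: float
    pipette: Optional[str]
    cell: Optional[int]
    kind: str
    payload: dict = field(default_factory=dict)


class ExperimentLog:
    """Ordered event records plus the cell map they refer to."""

    def __init__(self, cells: Optional[Iterable[CellSite]] = None):
        self.events: list[Event] = []
        self.cells: dict[int, CellSite] = {c.id: c for c in cells} if cells else {}

    def append(self, t, pipette, cell, kind, **payload) -> None:
        self.events.append(Event(t, pipette, cell, kind, payload))

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    @property
    def end_time(self) -> float:
        return self.events[-1].t if self.events else 0.0


# -- actions returned by the coordinator -------------------------------------


@dataclass(frozen=True)
class StartAttempt:
    pipette: str
    cell: int


@dataclass(frozen=True)
class StartClean:
    pipette: str


@dataclass(frozen=True)
class StartScreen:
    pipette_a: str
    pipette_b: str
    cell_a: int
    cell_b: int


@dataclass(frozen=True)
class Retire:
    pipette: str


@dataclass(frozen=True)
class SchedulerConfig:
    """Walk policy knobs.

    hold_limit_min
        Maximum time a cell is held in whole-cell configuration waiting for
        a partner (minutes); holds are released when it expires.
    collision_radius_um
        If set, a candidate cell closer than this to the other pipette's
        held cell is skipped during assignment (pipette-collision caution;
        off by default for a two-pipette rig).
    """

    hold_limit_min: float = 45.0
    collision_radius_um: Optional[float] = None


def euclidean(p: Sequence[float], q: Sequence[float]) -> float:
    return math.dist(p, q)


def select_next_cell(
    home: Sequence[float],
    queue: list[CellSite],
    avoid: Optional[Sequence[float]] = None,
    collision_radius: Optional[float] = None,
) -> CellSite:
    """Pop the queued cell nearest ``home`` (ties: lowest id); mark assigned.

    With ``avoid``/``collision_radius`` set, candidates within the radius of
    the other pipette's held cell are skipped. Raises :class:`QueueExhausted`
    when no eligible cell remains.
    """
    eligible = [
        c
        for c in queue
        if c.status == "queued"
        and (
            avoid is None
            or collision_radius is None
            or euclidean(c.position, avoid) >= collision_radius
        )
    ]
    if not eligible:
        raise QueueExhausted(f"no eligible cell remains for home {tuple(home)}")
    best = min(eligible, key=lambda c: (euclidean(c.position, home), c.id))
    queue.remove(best)
    best.status = "assigned"
    return best


class WalkCoordinator:
    """State machine for a two-pipette patch walk.

    Drive it by calling :meth:`start` once, then :meth:`advance` with each
    completion event; execute the returned actions (drawing durations and
    outcomes however the caller likes) and feed their completions back in.
    Events are ``(kind, pipette, t)`` with kinds ``hunt_done``,
    ``attempt_succeeded``, ``attempt_failed``, ``clean_done``,
    ``hold_expired``, plus ``screen_done`` which carries the two directed
    outcomes instead of a pipette.
    """

    def __init__(
        self,
        cells: Sequence[CellSite],
        homes: dict[str, tuple[float, float, float]],
        config: SchedulerConfig | None = None,
    ):
        if len(homes) != 2:
            raise ValueError("the walk coordinator drives exactly two pipettes")
        self.config = config or SchedulerConfig()
        self.queue: list[CellSite] = sorted(cells, key=lambda c: c.id)
        self.pipettes = {
            pid: PipetteAgent(id=pid, home_position=tuple(home))
            for pid, home in sorted(homes.items())
        }
        self.log = ExperimentLog(cells)
        self._assigned: dict[str, Optional[CellSite]] = {p: None for p in self.pipettes}
        self._stage_owner: Optional[str] = None
        self._stage_waiting: list[str] = []
        self._screening = False
        self._current_pair: Optional[dict] = None
        self.pairs: list[PairedRecording] = []

    # -- helpers -------------------------------------------------------------

    def _other(self, pid: str) -> PipetteAgent:
        (other,) = [p for p in self.pipettes.values() if p.id != pid]
        return other

    def _cell(self, cid: int) -> CellSite:
        return self.log.cells[cid]

    def _assign_and_try_start(self, pid: str, t: float) -> list:
        pip = self.pipettes[pid]
        other = self._other(pid)
        avoid = (
            self._cell(other.held_cell).position
            if other.held_cell is not None and self.config.collision_radius_um
            else None
        )
        try:
            cell = select_next_cell(
                pip.home_position, self.queue, avoid, self.config.collision_radius_um
            )
        except QueueExhausted:
            pip.stage = "retracted"
            self.log.append(t, pid, None, "retire")
            return [Retire(pid)]
        self._assigned[pid] = cell
        return self._try_start(pid, t)

    def _try_start(self, pid: str, t: float) -> list:
        """Grant the stage if free and begin the attempt, else queue for it."""
        pip = self.pipettes[pid]
        cell = self._assigned[pid]
        assert cell is not None
        if self._stage_owner is None:
            self._stage_owner = pid
            pip.stage = "hunting"
            self.log.append(t, pid, cell.id, "attempt_start")
            return [StartAttempt(pid, cell.id)]
        if pid not in self._stage_waiting:
            self._stage_waiting.append(pid)
        pip.stage = "moving"
        return []

    def _release_stage(self, pid: str, t: float) -> list:
        actions: list = []
        if self._stage_owner == pid:
            self._stage_owner = None
            if self._stage_waiting:
                nxt = self._stage_waiting.pop(0)
                actions += self._try_start(nxt, t)
        return actions

    def _release_hold(self, pid: str, t: float, status: CellStatus = "released") -> list:
        pip = self.pipettes[pid]
        cid = pip.held_cell
        assert cid is not None
        self._cell(cid).status = status
        pip.held_cell = None
        pip.whole_cell_since = None
        pip.stage = "cleaning"
        self.log.append(t, pid, cid, "release")
        self.log.append(t, pid, None, "clean_start")
        return [StartClean(pid)]

    # -- public API ----------------------------------------------------------

    def start(self, t: float = 0.0) -> list:
        """Assign each pipette its nearest cell; hand the stage to the first."""
        actions: list = []
        for pid in self.pipettes:
            actions += self._assign_and_try_start(pid, t)
        return actions

    def advance(self, kind: str, pipette: Optional[str], t: float, **payload) -> list:
        if pipette is not None:
            if pipette not in self.pipettes:
                raise ProtocolError(f"unknown pipette {pipette!r}")
            if self.pipettes[pipette].stage == "retracted":
                raise ProtocolError(f"event {kind!r} on retired pipette {pipette!r}")
        handler = getattr(self, f"_on_{kind}", None)
        if handler is None:
            raise ProtocolError(f"unknown event kind {kind!r}")
        return handler(pipette, t, **payload)

    # -- event handlers ------------------------------------------------------

    def _on_hunt_done(self, pid: str, t: float) -> list:
        pip = self.pipettes[pid]
        pip.stage = "sealing"
        self.log.append(t, pid, self._assigned[pid].id, "hunt_done")
        return self._release_stage(pid, t)

    def _on_attempt_succeeded(self, pid: str, t: float) -> list:
        pip = self.pipettes[pid]
        cell = self._assigned[pid]
        actions = self._release_stage(pid, t)  # covers failure before hunt_done
        pip.stage = "whole_cell"
        pip.held_cell = cell.id
        pip.whole_cell_since = t
        cell.status = "whole_cell"
        self._assigned[pid] = None
        self.log.append(t, pid, cell.id, "whole_cell")
        other = self._other(pid)
        if other.stage == "whole_cell":
            actions += self._begin_screen(t)
        return actions

    def _on_attempt_failed(self, pid: str, t: float) -> list:
        pip = self.pipettes[pid]
        cell = self._assigned[pid]
        actions = self._release_stage(pid, t)
        cell.status = "failed"
        self._assigned[pid] = None
        pip.stage = "cleaning"
        self.log.append(t, pid, cell.id, "attempt_failed")
        self.log.append(t, pid, None, "clean_start")
        return actions + [StartClean(pid)]

    def _on_clean_done(self, pid: str, t: float) -> list:
        self.log.append(t, pid, None, "clean_done")
        self.pipettes[pid].stage = "idle"
        return self._assign_and_try_start(pid, t)

    def _begin_screen(self, t: float) -> list:
        a, b = sorted(self.pipettes.values(), key=lambda p: p.id)
        self._screening = True
        self._current_pair = {
            "cell_a": a.held_cell,
            "cell_b": b.held_cell,
            "start": t,
        }
        self.log.append(
            t, None, None, "screen_start", cell_a=a.held_cell, cell_b=b.held_cell
        )
        return [StartScreen(a.id, b.id, a.held_cell, b.held_cell)]

    def _on_screen_done(
        self,
        pipette: None,
        t: float,
        outcome_ab: ProbeOutcome = "untested",
        outcome_ba: ProbeOutcome = "untested",
    ) -> list:
        if not self._screening or self._current_pair is None:
            raise ProtocolError("screen_done without a screen in progress")
        info = self._current_pair
        ca, cb = info["cell_a"], info["cell_b"]
        dist = euclidean(self._cell(ca).position, self._cell(cb).position)
        pair = PairedRecording(
            cell_a=ca,
            cell_b=cb,
            start=info["start"],
            end=t,
            intersomatic_distance=dist,
            probes=(
                DirectedProbe(ca, cb, outcome_ab),
                DirectedProbe(cb, ca, outcome_ba),
            ),
        )
        self.pairs.append(pair)
        self._screening = False
        self._current_pair = None
        self.log.append(
            t, None, None, "screen_done",
            cell_a=ca, cell_b=cb, outcome_ab=outcome_ab, outcome_ba=outcome_ba,
            distance_um=dist,
        )
        # walk rule: release the pipette that achieved whole cell first
        holders = [p for p in self.pipettes.values() if p.stage == "whole_cell"]
        first = min(holders, key=lambda p: (p.whole_cell_since, p.id))
        actions = self._release_hold(first.id, t)
        return actions

    def _on_hold_expired(self, pid: str, t: float) -> list:
        pip = self.pipettes[pid]
        if pip.stage != "whole_cell" or self._screening:
            return []  # stale timer: hold already ended or pair being screened
        return self._release_hold(pid, t)

    # -- terminal bookkeeping ------------------------------------------------

    def finish(self, t: float) -> None:
        """Release any remaining holds at end of experiment."""
        for pip in self.pipettes.values():
            if pip.stage == "whole_cell":
                cid = pip.held_cell
                self._cell(cid).status = "released"
                self.log.append(t, pip.id, cid, "release")
                pip.held_cell = None
                pip.stage = "retracted"

    @property
    def done(self) -> bool:
        return all(
            p.stage in ("retracted",) for p in self.pipettes.values()
        )


# -- log analysis -------------------------------------------------------------


def _hold_intervals(log: ExperimentLog) -> dict[str, list[tuple[int, float, float]]]:
    """Per-pipette (cell, start, end) whole-cell hold intervals from events."""
    open_holds: dict[str, tuple[int, float]] = {}
    intervals: dict[str, list[tuple[int, float, float]]] = {}
    for ev in log.events:
        if ev.kind == "whole_cell":
            if ev.pipette in open_holds:
                raise LogIntegrityError(
                    f"pipette {ev.pipette} entered whole cell at t={ev.t} while already holding"
                )
            open_holds[ev.pipette] = (ev.cell, ev.t)
        elif ev.kind == "release":
            if ev.pipette not in open_holds:
                raise LogIntegrityError(
                    f"pipette {ev.pipette} released at t={ev.t} without holding"
                )
            cid, t0 = open_holds.pop(ev.pipette)
            if ev.cell is not None and ev.cell != cid:
                raise LogIntegrityError(
                    f"pipette {ev.pipette} released cell {ev.cell} but held {cid}"
                )
            intervals.setdefault(ev.pipette, []).append((cid, t0, ev.t))
    end = log.end_time
    for pid, (cid, t0) in open_holds.items():
        intervals.setdefault(pid, []).append((cid, t0, end))
    return intervals


def pairs_from_log(log: ExperimentLog) -> tuple[list[PairedRecording], int]:
    """Paired recordings and the directed probed-connection count from a log.

    One :class:`PairedRecording` per maximal interval during which two
    distinct cells are co-held in whole-cell configuration; the probed count
    is twice the number of pairs. Screen outcomes recorded within an
    interval are attached; pairs without a completed screen carry
    ``untested`` probes.
    """
    intervals = _hold_intervals(log)
    pids = sorted(intervals)
    screens = [e for e in log.events if e.kind == "screen_done"]
    pairs: list[PairedRecording] = []
    for i, pa in enumerate(pids):
        for pb in pids[i + 1 :]:
            for ca, sa, ea in intervals[pa]:
                for cb, sb, eb in intervals[pb]:
                    start, end = max(sa, sb), min(ea, eb)
                    if end <= start:
                        continue
                    if ca == cb:
                        raise LogIntegrityError(
                            f"cell {ca} co-held by pipettes {pa} and {pb}"
                        )
                    if ca in log.cells and cb in log.cells:
                        dist = euclidean(
                            log.cells[ca].position, log.cells[cb].position
                        )
                    else:
                        dist = float("nan")
                    probes = (DirectedProbe(ca, cb), DirectedProbe(cb, ca))
                    for ev in screens:
                        if (
                            start <= ev.t <= end
                            and {ev.payload.get("cell_a"), ev.payload.get("cell_b")}
                            == {ca, cb}
                        ):
                            ab = ev.payload.get("outcome_ab", "untested")
                            ba = ev.payload.get("outcome_ba", "untested")
                            if ev.payload.get("cell_a") == ca:
                                probes = (DirectedProbe(ca, cb, ab), DirectedProbe(cb, ca, ba))
                            else:
                                probes = (DirectedProbe(ca, cb, ba), DirectedProbe(cb, ca, ab))
                    pairs.append(
                        PairedRecording(ca, cb, start, end, dist, probes)
                    )
    pairs.sort(key=lambda p: p.start)
    return pairs, 2 * len(pairs)
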