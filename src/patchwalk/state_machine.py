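"""Per-attempt patch-clamp stage rules as pure decision functions.

A patch attempt proceeds hunting -> gigaseal -> break-in -> whole cell; any
failure routes the pipette to cleaning. Each transition is gated by a rule
over electrical measurements:

* **neuron hunting** — the pipette descends in 0.1 um steps; a neuron is
  detected when tip resistance rises by >= 0.2 MOhm over 5 consecutive
  descending steps (endpoint difference over the window).
* **gigaseal** — seal resistance reaches 1 GOhm (>= 1000 MOhm); the
  controller then waits 5 s before attempting break-in.
* **break-in** — suction pulses (100-1000 ms, -345 mbar); success when
  resistance drops under 800 MOhm while the holding current at -70 mV
  stays above -200 pA.
* **recording QC** — whole-cell access resistance must stay below 40 MOhm
  for a recording to be included; above 50 MOhm the recording is stopped;
  the 40-50 MOhm band excludes the cell from analysis by default
  (configurable to stop instead).

These functions are pure so the simulator and tests can drive them with
synthetic traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "HuntTrace",
    "SealState",
    "RecordingQC",
    "Protocol",
    "GIGASEAL_THRESHOLD_MOHM",
    "GIGASEAL_WAIT_S",
    "BREAK_IN_RESISTANCE_MOHM",
    "HOLDING_CURRENT_FLOOR_PA",
    "detect_neuron",
    "gigaseal_reached",
    "break_in_success",
    "qc_evaluate",
    "build_current_clamp_protocol",
]

GIGASEAL_THRESHOLD_MOHM = 1000.0
GIGASEAL_WAIT_S = 5.0
BREAK_IN_RESISTANCE_MOHM = 800.0
HOLDING_CURRENT_FLOOR_PA = -200.0  # at -70 mV
HUNT_WINDOW_STEPS = 5
HUNT_THRESHOLD_MOHM = 0.2
HUNT_STEP_UM = 0.1


@dataclass(frozen=True)
class HuntTrace:
    """Resistance vs. pipette depth during neuron hunting.

    ``positions`` are strictly decreasing in 0.1 um increments (the pipette
    descends); ``resistances`` are tip resistances in MOhm at each step.
    """

    positions: np.ndarray
    resistances: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        res = np.asarray(self.resistances, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "resistances", res)
        if pos.shape != res.shape or pos.ndim != 1:
            raise ValueError("positions and resistances must be 1-D and equal length")
        if len(pos) > 1:
            steps = np.diff(pos)
            if not np.allclose(steps, -HUNT_STEP_UM, atol=1e-6):
                raise ValueError("positions must descend in 0.1 um steps")
        if np.any(res <= 0):
            raise ValueError("resistances must be positive")


@dataclass(frozen=True)
class SealState:
    """Seal resistance (MOhm) and holding current (pA at -70 mV)."""

    resistance: float
    holding_current: float = 0.0
    elapsed: float = 0.0

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise ValueError("resistance must be positive")


@dataclass(frozen=True)
class RecordingQC:
    """Whole-cell quality metrics; access resistance drives inclusion."""

    access_resistance: Sequence[float]
    capacitance: Optional[float] = None
    tau: Optional[float] = None
    input_resistance: Optional[float] = None
    resting_potential: Optional[float] = None


def detect_neuron(
    trace: HuntTrace,
    threshold_mohm: float = HUNT_THRESHOLD_MOHM,
    window: int = HUNT_WINDOW_STEPS,
) -> Optional[int]:
    """First step index at which the hunt criterion fires, or ``None``.

    The criterion is an endpoint difference: detection at the first index
    ``i`` with ``resistance[i] - resistance[i - window + 1] >= threshold``,
    evaluated over ``window`` consecutive descending steps. Fewer than
    ``window`` steps cannot detect (returns ``None``).
    """
    r = trace.resistances
    if len(r) < window:
        return None
    gains = r[window - 1 :] - r[: len(r) - window + 1]
    hits = np.nonzero(gains >= threshold_mohm)[0]
    if hits.size == 0:
        return None
    return int(hits[0] + window - 1)


def gigaseal_reached(state: SealState) -> bool:
    """True when seal resistance has reached 1 GOhm (>= 1000 MOhm).

    The downstream break-in transition fires only after a
    :data:`GIGASEAL_WAIT_S` settling wait, which belongs to the controller
    clock, not to this predicate.
    """
    return state.resistance >= GIGASEAL_THRESHOLD_MOHM


def break_in_success(state: SealState) -> bool:
    """True when break-in succeeded: R < 800 MOhm and holding current stays
    above -200 pA (at -70 mV)."""
    return (
        state.resistance < BREAK_IN_RESISTANCE_MOHM
        and state.holding_current >= HOLDING_CURRENT_FLOOR_PA
    )


def qc_evaluate(
    qc: RecordingQC,
    include_below_mohm: float = 40.0,
    stop_above_mohm: float = 50.0,
    band_action: Literal["exclude", "stop"] = "exclude",
) -> Literal["include", "stop", "exclude"]:
    """Classify a recording from its access-resistance series.

    ``include`` iff every access value is below 40 MOhm; ``stop`` (terminate
    recording, keep earlier data) when any value exceeds 50 MOhm; the 40-50
    MOhm band marks seal degradation and maps to ``band_action`` (default:
    exclude from analysis but keep recording).
    """
    access = np.asarray(qc.access_resistance, dtype=float)
    if access.size == 0:
        raise ValueError("access resistance series must be non-empty")
    if np.any(access <= 0):
        raise ValueError("access resistance must be positive")
    if np.any(access > stop_above_mohm):
        return "stop"
    if np.any(access >= include_below_mohm):
        return band_action
    return "include"


@dataclass(frozen=True)
class Protocol:
    """A current-clamp stimulus family: shared time base, one row per sweep."""

    time_s: np.ndarray
    sweeps_pa: np.ndarray  # shape (n_sweeps, n_samples)
    sweep_amplitudes_pa: np.ndarray

    @property
    def n_sweeps(self) -> int:
        return self.sweeps_pa.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] + (self.time_s[1] - self.time_s[0]))


def build_current_clamp_protocol(
    kind: Literal["whole_cell_check", "fi_curve"],
    step_pa: float = 100.0,
    sample_rate_hz: float = 10_000.0,
) -> Protocol:
    """Deterministic current-clamp stimulus waveforms.

    ``whole_cell_check``: a single 3 s sweep — 1 s at 0 pA, 1 s step of
    ``step_pa`` (|step| <= 300 pA), 1 s at 0 pA.

    ``fi_curve``: 16 sweeps of 3 s pulses from -20 to +280 pA in 20 pA
    steps, each preceded by a 2 s, -20 pA hyperpolarizing step ending
    500 ms before pulse onset (and a 500 ms tail at 0 pA).
    """
    dt = 1.0 / sample_rate_hz

    def seg(duration_s: float, level_pa: float) -> np.ndarray:
        return np.full(round(duration_s * sample_rate_hz), level_pa)

    if kind == "whole_cell_check":
        if abs(step_pa) > 300.0:
            raise ValueError("whole-cell check step must lie within -300..+300 pA")
        sweep = np.concatenate([seg(1.0, 0.0), seg(1.0, step_pa), seg(1.0, 0.0)])
        sweeps = sweep[None, :]
        amps = np.array([step_pa])
    elif kind == "fi_curve":
        amps = np.arange(-20.0, 280.0 + 1e-9, 20.0)
        rows = [
            np.concatenate(
                [seg(2.0, -20.0), seg(0.5, 0.0), seg(3.0, amp), seg(0.5, 0.0)]
            )
            for amp in amps
        ]
        sweeps = np.vstack(rows)
    else:
        raise ValueError(f"unknown protocol kind {kind!r}")
    time_s = np.arange(sweeps.shape[1]) * dt
    return Protocol(time_s=time_s, sweeps_pa=sweeps, sweep_amplitudes_pa=amps)
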