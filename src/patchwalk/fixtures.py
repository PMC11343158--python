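"""Seeded synthetic-data generators: cell maps and hunt traces.

These emulate the inputs a patch-walking session starts from, so every
module is testable without laboratory data:

* **cell maps** — a user selects 8-10 healthy somata spread over roughly a
  200 x 200 um cortical field, 20-100 um below the slice surface. The
  generator rejection-samples uniform positions honoring a minimum
  pairwise separation (default 15 um, about one soma diameter).
* **hunt traces** — tip resistance vs. depth during neuron hunting: flat
  baseline plus noise, with a resistance ramp beginning at the contact
  depth when a cell is present.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .scheduler import CellSite
from .state_machine import HuntTrace

__all__ = [
    "CellMapSpec",
    "generate_cell_map",
    "default_home_positions",
    "generate_hunt_trace",
]

_REJECTION_CAP = 10_000


@dataclass(frozen=True)
class CellMapSpec:
    """Geometry of a user-selected cell map (all lengths in um)."""

    n_cells: int = 9
    field_x_um: float = 200.0
    field_y_um: float = 200.0
    depth_band_um: tuple[float, float] = (20.0, 100.0)
    min_separation_um: float = 15.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        lo, hi = self.depth_band_um
        if not 0 <= lo < hi:
            raise ValueError("depth band must satisfy 0 <= lo < hi")
        if self.min_separation_um < 0:
            raise ValueError("min_separation must be non-negative")


def generate_cell_map(spec: CellMapSpec = CellMapSpec(), seed: Optional[int] = None,
                      rng: Optional[np.random.Generator] = None) -> list[CellSite]:
    """Uniform rejection-sampled cell positions honoring min separation.

    Deterministic under ``seed``; raises if the packing is infeasible
    within the bounded number of draws.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = spec.depth_band_um
    placed: list[np.ndarray] = []
    draws = 0
    while len(placed) < spec.n_cells:
        if draws >= _REJECTION_CAP:
            raise RuntimeError(
                f"could not place {spec.n_cells} cells with separation "
                f"{spec.min_separation_um} um in {draws} draws"
            )
        draws += 1
        cand = np.array(
            [
                rng.uniform(0.0, spec.field_x_um),
                rng.uniform(0.0, spec.field_y_um),
                rng.uniform(lo, hi),
            ]
        )
        if all(
            np.linalg.norm(cand - p) >= spec.min_separation_um for p in placed
        ):
            placed.append(cand)
    return [
        CellSite(id=i + 1, position=tuple(float(v) for v in pos))
        for i, pos in enumerate(placed)
    ]


def default_home_positions(spec: CellMapSpec = CellMapSpec()) -> dict[str, tuple[float, float, float]]:
    """Pipette homes at opposite field edges, giving each a natural half-field."""
    lo, hi = spec.depth_band_um
    mid_depth = (lo + hi) / 2.0
    y = spec.field_y_um / 2.0
    return {
        "a": (0.0, y, mid_depth),
        "b": (spec.field_x_um, y, mid_depth),
    }


def generate_hunt_trace(
    has_cell: bool,
    contact_depth_um: float = 50.0,
    baseline_mohm: float = 5.0,
    noise_sd_mohm: float = 0.0,
    seed: Optional[int] = None,
    start_depth_um: Optional[float] = None,
    n_steps: int = 60,
    ramp_mohm_per_step: float = 0.1,
) -> HuntTrace:
    """Synthetic neuron-hunting resistance trace over descending 0.1 um steps.

    Without a cell the trace is baseline plus optional Gaussian noise. With
    a cell, resistance ramps up by ``ramp_mohm_per_step`` on every step at
    or below ``contact_depth_um``, so the 0.2 MOhm / 5-step detection
    criterion fires within two steps of contact.
    """
    if noise_sd_mohm < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    start = start_depth_um if start_depth_um is not None else contact_depth_um + 2.0
    positions = start - 0.1 * np.arange(n_steps)
    res = np.full(n_steps, baseline_mohm)
    if has_cell:
        below = positions <= contact_depth_um + 1e-9
        res = res + ramp_mohm_per_step * np.cumsum(below)
    if noise_sd_mohm > 0:
        res = res + rng.normal(0.0, noise_sd_mohm, size=n_steps)
    res = np.maximum(res, 0.1)  # tip resistance stays physical
    return HuntTrace(positions=positions, resistances=res)
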