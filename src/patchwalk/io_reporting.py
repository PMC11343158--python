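"""File formats and reports: cell CSV, sweep CSV, event JSONL, summaries.

Cell maps are CSV with columns ``id, x_um, y_um, z_um`` (optional
``status``). Sweeps are long-form CSV ``time_ms, current_pA, sweep_id``.
Event logs are JSONL, one event per line with an explicit
``schema_version`` field. The connectivity-matrix report follows the
field's convention: cells labelled ``n.p`` (cell number plus pipette
letter), one row/column per cell, entries ``untested``,
``probed_not_connected``, or ``connected``; the two directions of a pair
are independent entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .connection_screen import ScreenResult, ScreenSweep
from .scheduler import (
    CellSite,
    Event,
    ExperimentLog,
    pairs_from_log,
)

__all__ = [
    "ParseError",
    "ConnectivityMatrixReport",
    "read_cells_csv",
    "write_cells_csv",
    "read_sweeps_csv",
    "write_sweeps_csv",
    "read_events_jsonl",
    "write_events_jsonl",
    "write_summary_csv",
    "build_connectivity_matrix",
]

SCHEMA_VERSION = 1
PathLike = Union[str, Path]


class ParseError(ValueError):
    """A file violated its schema; the message names the offending line/row."""


# -- cell maps -----------------------------------------------------------------

_CELL_COLUMNS = ["id", "x_um", "y_um", "z_um"]


def write_cells_csv(cells: Sequence[CellSite], path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "id": [c.id for c in cells],
            "x_um": [c.position[0] for c in cells],
            "y_um": [c.position[1] for c in cells],
            "z_um": [c.position[2] for c in cells],
            "status": [c.status for c in cells],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_cells_csv(path: PathLike) -> list[CellSite]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    cells = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cid = int(row.id)
            pos = (float(row.x_um), float(row.y_um), float(row.z_um))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed cell record at row {row_no}: {exc}") from exc
        status = getattr(row, "status", "queued")
        if not isinstance(status, str) or status != status:  # NaN guard
            status = "queued"
        cells.append(CellSite(id=cid, position=pos, status=status))
    return cells


# -- sweeps --------------------------------------------------------------------


def write_sweeps_csv(sweeps: Sequence[ScreenSweep], path: PathLike) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_ms": s.time_ms,
                "current_pA": s.current_pa,
                "sweep_id": s.sweep_index,
            }
        )
        for s in sweeps
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_sweeps_csv(path: PathLike) -> list[ScreenSweep]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["time_ms", "current_pA", "sweep_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    bad = df[df[["time_ms", "current_pA"]].isna().any(axis=1)]
    if len(bad):
        raise ParseError(f"{path}: malformed sweep sample at row {bad.index[0] + 2}")
    sweeps = []
    for sid, grp in df.groupby("sweep_id", sort=True):
        sweeps.append(
            ScreenSweep(
                time_ms=grp["time_ms"].to_numpy(float),
                current_pa=grp["current_pA"].to_numpy(float),
                sweep_index=int(sid),
            )
        )
    return sweeps


# -- event logs ----------------------------------------------------------------


def write_events_jsonl(log: ExperimentLog, path: PathLike) -> None:
    with open(path, "w") as fh:
        for ev in log.events:
            fh.write(
                json.dumps(
                    {
                        "schema_version": SCHEMA_VERSION,
                        "t": ev.t,
                        "pipette": ev.pipette,
                        "cell": ev.cell,
                        "kind": ev.kind,
                        "payload": ev.payload,
                    }
                )
                + "\n"
            )


def read_events_jsonl(path: PathLike, cells: Optional[Sequence[CellSite]] = None) -> ExperimentLog:
    log = ExperimentLog(cells)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: invalid JSON at line {line_no}: {exc}") from exc
            for key in ("t", "kind"):
                if key not in rec:
                    raise ParseError(f"{path}: line {line_no} missing field {key!r}")
            log.events.append(
                Event(
                    t=float(rec["t"]),
                    pipette=rec.get("pipette"),
                    cell=rec.get("cell"),
                    kind=rec["kind"],
                    payload=rec.get("payload", {}),
                )
            )
    return log


def write_summary_csv(summary, path: PathLike) -> None:
    """Flat one-row CSV of a :class:`~patchwalk.simulator.LogSummary`."""
    row = {
        "attempts": summary.attempts,
        "whole_cells": summary.whole_cells,
        "failures": summary.failures,
        "success_rate_pct": summary.success_rate_pct,
        "pairs": summary.pairs,
        "probed_connections": summary.probed_connections,
        "found_connections": summary.found_connections,
        "total_time_min": summary.total_time_min,
    }
    pd.DataFrame([row]).to_csv(path, index=False)


# -- connectivity matrix -------------------------------------------------------


@dataclass
class ConnectivityMatrixReport:
    """Cell-by-cell connection-screen report with ``n.p`` labels."""

    labels: list[str]
    matrix: pd.DataFrame  # entries: self / untested / probed_not_connected / connected

    @property
    def n_probed(self) -> int:
        vals = self.matrix.to_numpy()
        return int(np.sum((vals == "probed_not_connected") | (vals == "connected")))

    @property
    def n_connected(self) -> int:
        return int(np.sum(self.matrix.to_numpy() == "connected"))

    def to_csv(self, path: PathLike) -> None:
        self.matrix.to_csv(path, index_label="pre\\post")


def _log_cell_ids(log: ExperimentLog) -> list[int]:
    """All cell ids the log knows about (cell map plus event references)."""
    ids = set(log.cells)
    for ev in log.events:
        if ev.cell is not None:
            ids.add(ev.cell)
        for key in ("cell_a", "cell_b"):
            if key in ev.payload and ev.payload[key] is not None:
                ids.add(ev.payload[key])
    return sorted(ids)


def _cell_pipette_labels(log: ExperimentLog) -> dict[int, str]:
    """Label each patched cell ``n.p``: cell number + the pipette letter that
    held it; unpatched cells keep a bare number."""
    holder: dict[int, str] = {}
    for ev in log.events:
        if ev.kind == "whole_cell" and ev.cell is not None:
            holder[ev.cell] = ev.pipette or "?"
    return {
        cid: f"{cid}.{holder[cid]}" if cid in holder else str(cid)
        for cid in _log_cell_ids(log)
    }


def build_connectivity_matrix(
    log: ExperimentLog,
    screens: Optional[Sequence[ScreenResult]] = None,
) -> ConnectivityMatrixReport:
    """Assemble the connectivity matrix from a log and optional screen results.

    Directed outcomes come from the log's completed screens; additional
    :class:`ScreenResult` records (e.g. re-analysed offline) may override
    them, but must reference cells probed together in the log — an orphan
    result is an error. Exactly ``2 x pairs`` off-diagonal entries are
    non-untested when every pair was screened.
    """
    pairs, _ = pairs_from_log(log)
    labels_by_id = _cell_pipette_labels(log)
    ids = _log_cell_ids(log)
    labels = [labels_by_id[i] for i in ids]
    mat = pd.DataFrame("untested", index=labels, columns=labels)
    for lab in labels:
        mat.loc[lab, lab] = "self"
    probed_dirs = set()
    for pair in pairs:
        for probe in pair.probes:
            probed_dirs.add((probe.pre, probe.post))
            if probe.outcome != "untested":
                mat.loc[labels_by_id[probe.pre], labels_by_id[probe.post]] = (
                    "connected" if probe.outcome == "connected" else "probed_not_connected"
                )
    for res in screens or []:
        if (res.pre, res.post) not in probed_dirs:
            raise ValueError(
                f"orphan screen result {res.pre}->{res.post}: cells were never co-held in the log"
            )
        if not res.tested:
            continue
        mat.loc[labels_by_id[res.pre], labels_by_id[res.post]] = (
            "connected" if res.connected else "probed_not_connected"
        )
    return ConnectivityMatrixReport(labels=labels, matrix=mat)
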