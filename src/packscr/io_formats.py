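"""Readers and writers for the three SCR input files and detection-event tables.

The package works with three plain-CSV files, mirroring the classic SCR
program layout:

* a **trap deployment file** (``trap_id,x,y,occ_1..occ_K``) giving projected
  planar coordinates in metres and a binary activity flag per sampling
  occasion;
* an **animal capture file** (``animal_id,trap_id,occasion`` triples, one row
  per capture event) — the binary encounter data;
* a **state-space file** (``x,y,habitat``) listing candidate activity-centre
  points on a regular lattice.

Raw detection events (``animal_id,trap_id,timestamp``) are the upstream form
from which occasions are assigned and the capture file is built.

All readers validate eagerly and fail with the offending row/ID rather than
silently coercing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class RunLog:
    """Plain-text run log collecting counts of dropped/collapsed records."""

    def __init__(self) -> None:
        self.messages: list[str] = []

    def info(self, msg: str) -> None:
        self.messages.append(msg)

    def warn(self, msg: str) -> None:
        self.messages.append("WARNING: " + msg)

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.messages) + "\n")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return "\n".join(self.messages)


@dataclass
class TrapDeployment:
    """One camera-trap station with its per-occasion activity flags."""

    trap_id: str
    x: float
    y: float
    active: np.ndarray  # (K,) 0/1

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=np.int8)
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"trap {self.trap_id!r}: non-finite coordinates")
        if not np.isin(self.active, (0, 1)).all():
            raise ValueError(f"trap {self.trap_id!r}: activity flags must be 0/1")
        if self.active.sum() == 0:
            raise ValueError(f"trap {self.trap_id!r}: no active occasion")


@dataclass
class DetectionEvent:
    """One independent video capture of a focal animal at a trap."""

    animal_id: str
    trap_id: str
    timestamp: datetime
    session_id: str = ""


@dataclass
class SessionConfig:
    """Session window and occasion anchoring.

    A sampling occasion spans 24 h anchored at ``occasion_boundary_hour``
    (default 15:00), so that nocturnal activity is not split across two
    occasions (the "midnight problem"): an event at or after the boundary
    hour belongs to the occasion opening that day.
    """

    session_id: str
    start_date: date
    n_occasions: int
    occasion_boundary_hour: int = 15
    blocks: Optional[dict] = None

    def __post_init__(self) -> None:
        if isinstance(self.start_date, str):
            self.start_date = date.fromisoformat(self.start_date)
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be >= 1")
        if not (0 <= self.occasion_boundary_hour < 24):
            raise ValueError("occasion_boundary_hour must be in [0, 24)")

    @property
    def start(self) -> datetime:
        return datetime(
            self.start_date.year,
            self.start_date.month,
            self.start_date.day,
            self.occasion_boundary_hour,
        )


def trap_coords(traps: Sequence[TrapDeployment]) -> np.ndarray:
    """(J, 2) array of trap coordinates in deployment order."""
    return np.array([[t.x, t.y] for t in traps], dtype=float)


def activity_matrix(traps: Sequence[TrapDeployment]) -> np.ndarray:
    """(J, K) binary trap-by-occasion activity matrix."""
    return np.stack([t.active for t in traps]).astype(np.int8)


def read_trap_file(path: str | os.PathLike) -> list[TrapDeployment]:
    """Read a trap deployment CSV (``trap_id,x,y,occ_1..occ_K``).

    K is inferred from the header; row order is preserved.  Duplicate trap
    IDs and non-binary activity flags are rejected with the offending row.
    """
    df = pd.read_csv(path, dtype={"trap_id": str}, float_precision="round_trip")
    required = ["trap_id", "x", "y"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"trap file missing column {col!r}")
    occ_cols = [c for c in df.columns if c.startswith("occ_")]
    if not occ_cols:
        raise ValueError("trap file has no occasion columns (occ_1..occ_K)")
    occ_cols = sorted(occ_cols, key=lambda c: int(c.split("_")[1]))
    dup = df["trap_id"][df["trap_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate trap_id(s): {sorted(set(dup))}")
    traps = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        flags = np.asarray([getattr(row, c) for c in occ_cols])
        if not np.isin(flags, (0, 1)).all():
            bad = flags[~np.isin(flags, (0, 1))][0]
            raise ValueError(
                f"trap file row {row_number}: non-binary activity flag {bad!r}"
            )
        traps.append(TrapDeployment(row.trap_id, float(row.x), float(row.y), flags))
    return traps


def read_events(
    path: str | os.PathLike,
    config: SessionConfig,
    known_trap_ids: Optional[Sequence[str]] = None,
    log: Optional[RunLog] = None,
) -> list[DetectionEvent]:
    """Read a detection-event CSV (``animal_id,trap_id,timestamp``).

    Events outside the session window are dropped and counted in the log.
    Unknown trap IDs (when ``known_trap_ids`` is given) are an error.
    """
    from .capture_history import assign_occasion

    df = pd.read_csv(path, dtype={"animal_id": str, "trap_id": str})
    for col in ("animal_id", "trap_id", "timestamp"):
        if col not in df.columns:
            raise ValueError(f"event file missing column {col!r}")
    if known_trap_ids is not None:
        unknown = sorted(set(df["trap_id"]) - set(known_trap_ids))
        if unknown:
            raise ValueError(f"unknown trap_id(s) in event file: {unknown}")
    events, n_dropped = [], 0
    for row in df.itertuples(index=False):
        ts = datetime.fromisoformat(str(row.timestamp))
        if assign_occasion(ts, config) is None:
            n_dropped += 1
            continue
        events.append(DetectionEvent(row.animal_id, row.trap_id, ts, config.session_id))
    if log is not None:
        log.info(
            f"read_events: {len(events)} events retained, "
            f"{n_dropped} outside session window dropped"
        )
    return events


# ---------------------------------------------------------------------------
# Three-file SCR bundle (capture / trap deployment / state space)
# ---------------------------------------------------------------------------

_CAPTURE_FILE = "captures.csv"
_TRAP_FILE = "traps.csv"
_STATESPACE_FILE = "statespace.csv"


def write_spacecap_inputs(history, traps, statespace, directory) -> tuple[str, str, str]:
    """Write the three standard SCR input files to ``directory``.

    Returns the three paths (captures, traps, state space).  A subsequent
    :func:`read_spacecap_inputs` reproduces the arrays bit-exactly.
    """
    n, J, K = history.y.shape
    if J != len(traps):
        raise ValueError("history/traps dimension mismatch")
    if (history.y.sum(axis=(1, 2)) == 0).any():
        bad = [history.animal_ids[i] for i in np.where(history.y.sum(axis=(1, 2)) == 0)[0]]
        raise ValueError(f"all-zero capture history row(s) for animal(s): {bad}")
    act = activity_matrix(traps)
    if act.shape[1] != K:
        raise ValueError("trap activity length does not match history occasions")
    os.makedirs(directory, exist_ok=True)

    rows = []
    for i, j, k in zip(*np.nonzero(history.y)):
        rows.append((history.animal_ids[i], traps[j].trap_id, k + 1))
    cap = pd.DataFrame(rows, columns=["animal_id", "trap_id", "occasion"])
    cap_path = os.path.join(directory, _CAPTURE_FILE)
    cap.to_csv(cap_path, index=False)

    tdf = pd.DataFrame(
        {
            "trap_id": [t.trap_id for t in traps],
            "x": [t.x for t in traps],
            "y": [t.y for t in traps],
        }
    )
    for k in range(K):
        tdf[f"occ_{k + 1}"] = act[:, k]
    trap_path = os.path.join(directory, _TRAP_FILE)
    tdf.to_csv(trap_path, index=False)

    sdf = pd.DataFrame(
        {
            "x": statespace.points[:, 0],
            "y": statespace.points[:, 1],
            "habitat": statespace.habitat.astype(int),
        }
    )
    ss_path = os.path.join(directory, _STATESPACE_FILE)
    sdf.to_csv(ss_path, index=False)
    return cap_path, trap_path, ss_path


def read_statespace_file(path: str | os.PathLike, spacing_m: Optional[float] = None):
    """Read a state-space CSV (``x,y,habitat``).

    ``spacing_m`` may be given explicitly; otherwise it is inferred as the
    minimum nearest-neighbour distance among points.
    """
    from .statespace import StateSpace

    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("x", "y", "habitat"):
        if col not in df.columns:
            raise ValueError(f"state-space file missing column {col!r}")
    hab = df["habitat"].to_numpy()
    if not np.isin(hab, (0, 1)).all():
        raise ValueError("habitat flags must be 0/1")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    if spacing_m is None:
        from scipy.spatial import cKDTree

        if len(pts) < 2:
            raise ValueError("cannot infer spacing from fewer than 2 points")
        d, _ = cKDTree(pts).query(pts, k=2)
        spacing_m = float(d[:, 1].min())
    return StateSpace(points=pts, habitat=hab.astype(np.int8), spacing_m=spacing_m)


def read_spacecap_inputs(directory, session_id: str = ""):
    """Read back a three-file bundle written by :func:`write_spacecap_inputs`.

    Returns ``(CaptureHistory, traps, StateSpace)``.  Animal order is the
    order of first appearance in the capture file (which preserves the order
    they were written in).
    """
    from .capture_history import CaptureHistory

    traps = read_trap_file(os.path.join(directory, _TRAP_FILE))
    space = read_statespace_file(os.path.join(directory, _STATESPACE_FILE))
    cap = pd.read_csv(
        os.path.join(directory, _CAPTURE_FILE),
        dtype={"animal_id": str, "trap_id": str},
    )
    K = activity_matrix(traps).shape[1]
    trap_index = {t.trap_id: j for j, t in enumerate(traps)}
    animal_ids = list(dict.fromkeys(cap["animal_id"]))
    animal_index = {a: i for i, a in enumerate(animal_ids)}
    y = np.zeros((len(animal_ids), len(traps), K), dtype=np.int8)
    for row in cap.itertuples(index=False):
        if row.trap_id not in trap_index:
            raise ValueError(f"capture file references unknown trap {row.trap_id!r}")
        if not (1 <= row.occasion <= K):
            raise ValueError(f"capture occasion {row.occasion} outside 1..{K}")
        y[animal_index[row.animal_id], trap_index[row.trap_id], row.occasion - 1] = 1
    history = CaptureHistory(y=y, animal_ids=animal_ids,
                             trap_ids=[t.trap_id for t in traps],
                             session_id=session_id)
    return history, traps, space
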