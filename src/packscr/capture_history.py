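"""Pack-level binary capture histories and encounter summaries.

A capture event (CE) is one detection of a focal animal at one trap in one
24-h occasion, regardless of how many videos were recorded.  The encounter
model is Bernoulli: a pack can be detected at most once per trap per
occasion, so multiple events of the same animal/trap/occasion collapse to a
single 1 in the binary history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    DetectionEvent,
    RunLog,
    SessionConfig,
    TrapDeployment,
    activity_matrix,
    trap_coords,
)


@dataclass
class CaptureHistory:
    """Binary animals x traps x occasions encounter array."""

    y: np.ndarray  # (n, J, K) 0/1
    animal_ids: list[str]
    trap_ids: list[str]
    session_id: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.y.ndim != 3:
            raise ValueError("y must be (n_animals, n_traps, n_occasions)")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary")
        if self.y.shape[0] != len(self.animal_ids):
            raise ValueError("animal_ids length mismatch")
        if self.y.shape[1] != len(self.trap_ids):
            raise ValueError("trap_ids length mismatch")

    @property
    def n_animals(self) -> int:
        return self.y.shape[0]

    @property
    def n_traps(self) -> int:
        return self.y.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[2]

    @property
    def n_ce(self) -> int:
        """Total number of capture events (1s in the binary array)."""
        return int(self.y.sum())


@dataclass
class MMDMResult:
    """Mean maximum distance moved over animals captured at > 1 trap.

    ``mean``/``sd`` are NaN when no animal contributes (undefined, not 0).
    """

    mean: float
    sd: float
    n: int
    n_single_trap: int

    @property
    def defined(self) -> bool:
        return self.n > 0


@dataclass
class EncounterSummary:
    n_ce: int
    trap_days: int
    ce_rate: float
    traps_per_animal: float
    mmdm: MMDMResult


def assign_occasion(timestamp: datetime, config: SessionConfig) -> Optional[int]:
    """Map a timestamp to its 1-based sampling occasion, or None if outside
    the session window.

    Occasion k covers ``[start + (k-1)*24h, start + k*24h)`` where ``start``
    is the session start date at the boundary hour (15:00 by default): an
    event at or after the boundary hour belongs to the occasion opening that
    day; an earlier event belongs to the occasion opened the previous day.
    """
    delta = timestamp - config.start
    k = math.floor(delta.total_seconds() / 86400.0) + 1
    if 1 <= k <= config.n_occasions:
        return k
    return None


def build_history(
    events: Sequence[DetectionEvent],
    traps: Sequence[TrapDeployment],
    config: SessionConfig,
    log: Optional[RunLog] = None,
) -> CaptureHistory:
    """Collapse detection events into a binary pack-level capture history.

    Multiple events of one animal at one trap in one occasion collapse to a
    single capture event; events at inactive trap-occasions are dropped with
    a logged warning, and animals left with no captures are removed.
    """
    if len(events) == 0:
        raise ValueError("empty history: no detection events")
    trap_index = {t.trap_id: j for j, t in enumerate(traps)}
    unknown = sorted({e.trap_id for e in events} - set(trap_index))
    if unknown:
        raise ValueError(f"events reference unknown trap(s): {unknown}")
    act = activity_matrix(traps)
    K = config.n_occasions
    if act.shape[1] != K:
        raise ValueError("trap activity length does not match n_occasions")

    animal_ids = list(dict.fromkeys(e.animal_id for e in events))
    animal_index = {a: i for i, a in enumerate(animal_ids)}
    y = np.zeros((len(animal_ids), len(traps), K), dtype=np.int8)
    n_outside = n_inactive = 0
    for e in events:
        k = assign_occasion(e.timestamp, config)
        if k is None:
            n_outside += 1
            continue
        j = trap_index[e.trap_id]
        if act[j, k - 1] == 0:
            n_inactive += 1
            continue
        y[animal_index[e.animal_id], j, k - 1] = 1

    if log is not None:
        if n_outside:
            log.warn(f"build_history: {n_outside} event(s) outside session window dropped")
        if n_inactive:
            log.warn(f"build_history: {n_inactive} event(s) at inactive trap-occasions dropped")

    detected = y.sum(axis=(1, 2)) > 0
    if not detected.all():
        removed = [a for a, d in zip(animal_ids, detected) if not d]
        if log is not None:
            log.warn(
                f"build_history: animal(s) {removed} had captures only in dropped "
                "records and were removed"
            )
        y = y[detected]
        animal_ids = [a for a, d in zip(animal_ids, detected) if d]
    if len(animal_ids) == 0:
        raise ValueError("empty history: all events dropped")
    return CaptureHistory(
        y=y,
        animal_ids=animal_ids,
        trap_ids=[t.trap_id for t in traps],
        session_id=config.session_id,
    )


def ce_rate(n_ce: int, trap_days: float) -> float:
    """Capture events per 100 trap-days."""
    if trap_days <= 0:
        raise ValueError("trap_days must be positive")
    return 100.0 * n_ce / trap_days


def mmdm(history: CaptureHistory, traps: Sequence[TrapDeployment]) -> MMDMResult:
    """Mean maximum distance moved (metres) over animals captured at more
    than one trap; animals captured at a single trap are excluded from the
    mean but counted separately.  SD uses the n-1 denominator."""
    coords = trap_coords(traps)
    maxima = []
    n_single = 0
    for i in range(history.n_animals):
        trap_idx = np.where(history.y[i].sum(axis=1) > 0)[0]
        if len(trap_idx) < 2:
            n_single += 1
            continue
        pts = coords[trap_idx]
        diffs = pts[:, None, :] - pts[None, :, :]
        maxima.append(float(np.sqrt((diffs**2).sum(axis=2)).max()))
    n = len(maxima)
    if n == 0:
        return MMDMResult(mean=math.nan, sd=math.nan, n=0, n_single_trap=n_single)
    mean = float(np.mean(maxima))
    sd = float(np.std(maxima, ddof=1)) if n > 1 else math.nan
    return MMDMResult(mean=mean, sd=sd, n=n, n_single_trap=n_single)


def pack_size_estimate(counts_per_event: Sequence[int]) -> int:
    """Pack size as the maximum number of individuals recorded in a single
    capture event."""
    counts = list(counts_per_event)
    if len(counts) == 0:
        raise ValueError("no capture events with counts")
    return max(counts)


def summarize(
    history: CaptureHistory, traps: Sequence[TrapDeployment]
) -> EncounterSummary:
    """Encounter summary: CE count, effort, CE rate, traps/animal, MMDM."""
    act = activity_matrix(traps)
    trap_days = int(act.sum())
    n_ce = history.n_ce
    traps_per_animal = float(
        np.mean((history.y.sum(axis=2) > 0).sum(axis=1))
    )
    return EncounterSummary(
        n_ce=n_ce,
        trap_days=trap_days,
        ce_rate=ce_rate(n_ce, trap_days),
        traps_per_animal=traps_per_animal,
        mmdm=mmdm(history, traps),
    )
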