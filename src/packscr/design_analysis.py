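"""Survey-design robustness analyses.

Three analyses mirror how a camera-trap SCR design can be stress-tested:
reducing the trap array, truncating the session to shorter durations, and
quantifying inter-observer agreement in pack assignment together with its
effect on the capture history.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .capture_history import CaptureHistory
from .io_formats import RunLog, TrapDeployment

INDETERMINATE = "indeterminate"

#: Per-video pack assignments: rows = videos, columns = observers, values =
#: pack labels or "indeterminate".  A plain DataFrame; validated on use.
AgreementTable = pd.DataFrame


def subset_traps(
    history: CaptureHistory,
    traps: Sequence[TrapDeployment],
    keep_ids: Sequence[str],
    log: Optional[RunLog] = None,
) -> tuple[CaptureHistory, list[TrapDeployment]]:
    """Restrict a capture history to a subset of traps.

    Captures at removed traps are dropped; animals left without captures are
    removed (logged).  The state space can be regenerated around the
    remaining traps separately via :func:`packscr.statespace.generate_grid`.
    """
    keep = list(dict.fromkeys(keep_ids))
    if len(keep) == 0:
        raise ValueError("empty trap keep-set")
    unknown = sorted(set(keep) - set(history.trap_ids))
    if unknown:
        raise ValueError(f"keep_ids not in history: {unknown}")
    idx = [history.trap_ids.index(t) for t in keep]
    y = history.y[:, idx, :]
    detected = y.sum(axis=(1, 2)) > 0
    if not detected.all() and log is not None:
        removed = [a for a, d in zip(history.animal_ids, detected) if not d]
        log.warn(f"subset_traps: animal(s) {removed} lost all captures and were removed")
    y = y[detected]
    animal_ids = [a for a, d in zip(history.animal_ids, detected) if d]
    if len(animal_ids) == 0:
        raise ValueError("no animals remain after trap subsetting")
    traps_by_id = {t.trap_id: t for t in traps}
    new_traps = [traps_by_id[t] for t in keep]
    return (
        CaptureHistory(y=y, animal_ids=animal_ids, trap_ids=keep,
                       session_id=history.session_id),
        new_traps,
    )


@dataclass
class TruncationResult:
    history: CaptureHistory
    n_days: int
    n_detected: int
    n_recaptures: int  # capture events beyond each animal's first
    traps: Optional[list] = None  # deployments with matching truncated effort


def truncate_session(
    history: CaptureHistory, n_days: int,
    traps: Optional[Sequence[TrapDeployment]] = None,
) -> TruncationResult:
    """Keep only the first ``n_days`` occasions (anchored at session start).

    Animals without captures in the truncated window are dropped; the
    recapture count (CEs beyond each animal's first) is reported so the
    effect of session length on information content can be tracked.  When
    ``traps`` are given, deployments with correspondingly truncated
    activity vectors are returned alongside.
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    if n_days > history.n_occasions:
        raise ValueError(
            f"n_days {n_days} exceeds session length {history.n_occasions}"
        )
    y = history.y[:, :, :n_days]
    detected = y.sum(axis=(1, 2)) > 0
    y = y[detected]
    animal_ids = [a for a, d in zip(history.animal_ids, detected) if d]
    if len(animal_ids) == 0:
        raise ValueError("no animals detected within the truncated window")
    truncated = CaptureHistory(y=y, animal_ids=animal_ids,
                               trap_ids=list(history.trap_ids),
                               session_id=history.session_id)
    new_traps = None
    if traps is not None:
        new_traps = [
            TrapDeployment(t.trap_id, t.x, t.y, t.active[:n_days]) for t in traps
        ]
    return TruncationResult(
        history=truncated,
        n_days=n_days,
        n_detected=truncated.n_animals,
        n_recaptures=truncated.n_ce - truncated.n_animals,
        traps=new_traps,
    )


def _check_table(table: AgreementTable) -> AgreementTable:
    if table.isna().any().any():
        raise ValueError("ragged agreement table: missing assignments")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 observers")
    return table


@dataclass
class AgreementStats:
    match_pct: pd.DataFrame  # observer x observer percent of identical calls
    n_videos: int
    packs_per_observer: dict  # distinct non-indeterminate labels
    ce_per_observer: dict  # non-indeterminate assignments


def agreement_stats(
    table: AgreementTable, reference_observer: Optional[str] = None
) -> AgreementStats:
    """Pairwise percent agreement in pack assignment plus per-observer
    distinct-pack and capture-history sizes.

    Indeterminate is treated as a label, so two observers both calling a
    video indeterminate count as a match.
    """
    table = _check_table(table)
    obs = list(table.columns)
    if reference_observer is not None and reference_observer not in obs:
        raise ValueError(f"unknown reference observer {reference_observer!r}")
    V = len(table)
    pct = pd.DataFrame(np.full((len(obs), len(obs)), 100.0), index=obs, columns=obs)
    for a in range(len(obs)):
        for b in range(a + 1, len(obs)):
            matches = int((table[obs[a]] == table[obs[b]]).sum())
            pct.iloc[a, b] = pct.iloc[b, a] = 100.0 * matches / V
    packs = {
        o: int(table[o][table[o] != INDETERMINATE].nunique()) for o in obs
    }
    ces = {o: int((table[o] != INDETERMINATE).sum()) for o in obs}
    return AgreementStats(match_pct=pct, n_videos=V,
                          packs_per_observer=packs, ce_per_observer=ces)


def concordant_history(
    table: AgreementTable, observers: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Keep only videos on which all selected observers agree on a
    non-indeterminate pack; returns the filtered table."""
    table = _check_table(table)
    obs = list(observers) if observers is not None else list(table.columns)
    if len(obs) < 2:
        raise ValueError("need at least 2 observers")
    sub = table[obs]
    agree = sub.nunique(axis=1) == 1
    determinate = (sub != INDETERMINATE).all(axis=1)
    out = table[agree & determinate]
    if len(out) == 0:
        raise ValueError("no concordant non-indeterminate events")
    return out
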