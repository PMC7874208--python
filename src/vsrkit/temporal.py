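"""Trial-level fatigue and recovery statistics.

Four summaries of the time course of the VSR over a trial:

* **half-time** — when the normalized-integral response first falls to half
  its initial baseline and stays there, a per-larva measure of how fast the
  reflex runs down;
* **percentage of active cycles**;
* **pauses** — maximal runs of at least two consecutive inactive cycles,
  reported as durations;
* **minimal recovery interval** — for defined-interval protocols (stimuli
  separated by decreasing rests), the shortest rest after which activity
  resumed following a loss of activity.  A larva that never loses activity
  needs no recovery time and reports 0.

All operate on the retained-cycle table produced by
:func:`vsrkit.metrics.analyze_trace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTrialError,
    InsufficientDataError,
    ProtocolError,
    UndefinedHalfTimeError,
)

__all__ = [
    "TrialResult",
    "half_time",
    "pauses",
    "pct_active",
    "min_recovery_interval",
    "summarize_trial",
]

#: Cycles averaged for the half-time baseline and the smoothing span.
BASELINE_CYCLES = 3
SMOOTH_CYCLES = 3

#: Minimum consecutive inactive cycles that constitute a pause.
MIN_PAUSE_RUN = 2


@dataclass
class TrialResult:
    """Per-trial temporal statistics.

    ``half_time_s`` and ``min_recovery_interval_s`` are ``None`` when the
    quantity is undefined for the trial (response never halves / no
    interval protocol / activity never resumes).
    """

    larva_id: str
    per_cycle: pd.DataFrame
    half_time_s: float | None
    pct_active: float
    pauses_s: list[float]
    min_recovery_interval_s: float | None
    n_retained: int
    n_excluded_startle: int
    genotype: str | None = None

    def to_dict(self) -> dict:
        return {
            "larva_id": self.larva_id,
            "genotype": self.genotype,
            "half_time_s": self.half_time_s,
            "pct_active": self.pct_active,
            "pauses_s": list(self.pauses_s),
            "min_recovery_interval_s": self.min_recovery_interval_s,
            "n_retained": self.n_retained,
            "n_excluded_startle": self.n_excluded_startle,
        }


def _smooth(values: np.ndarray, span: int = SMOOTH_CYCLES) -> np.ndarray:
    """Centered moving average whose window shrinks symmetrically at edges."""
    n = len(values)
    h = span // 2
    out = np.empty(n)
    for i in range(n):
        k = min(h, i, n - 1 - i)
        out[i] = values[i - k : i + k + 1].mean()
    return out


def half_time(times_s: Sequence[float], integrals: Sequence[float]) -> float | None:
    """Time at which the smoothed normalized-integral response halves.

    The baseline is the mean of the first three cycles' normalized
    integrals.  The per-cycle series is smoothed with a centered 3-cycle
    moving average, and the half-time is the linearly interpolated time
    (between cycle midpoints) at which the smoothed series first reaches
    half the baseline and stays at or below it for the following cycle.
    Returns ``None`` when the response never halves.

    Parameters
    ----------
    times_s
        Cycle midpoint times of the retained cycles, in seconds.
    integrals
        Normalized integral (degrees) of each retained cycle.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(integrals, dtype=float)
    if len(t) != len(v):
        raise ValueError("times and integrals must have equal length")
    if len(v) < 4:
        raise InsufficientDataError("half-time needs at least 4 retained cycles")
    baseline = float(v[:BASELINE_CYCLES].mean())
    if baseline <= 0:
        raise UndefinedHalfTimeError("no initial response: baseline is zero")
    half = baseline / 2.0
    s = _smooth(v)
    for i in range(len(s) - 1):
        if s[i] <= half and s[i + 1] <= half:
            if i == 0 or s[i - 1] <= half:
                return float(t[i])
            frac = (s[i - 1] - half) / (s[i - 1] - s[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None


def pauses(active: Sequence[bool], cycle_duration_s: float) -> list[float]:
    """Durations of maximal runs of >= 2 consecutive inactive retained cycles.

    Rest epochs between stimuli neither break nor count toward a run: the
    ``active`` sequence is simply the retained cycles in order across the
    whole trial, and durations are stimulated time only.
    """
    a = np.asarray(active, dtype=bool)
    out: list[float] = []
    run = 0
    for flag in a:
        if not flag:
            run += 1
        else:
            if run >= MIN_PAUSE_RUN:
                out.append(run * cycle_duration_s)
            run = 0
    if run >= MIN_PAUSE_RUN:
        out.append(run * cycle_duration_s)
    return out


def pct_active(active: Sequence[bool]) -> float:
    """Percentage of retained cycles that are active."""
    a = np.asarray(active, dtype=bool)
    if len(a) == 0:
        raise DegenerateTrialError("no retained cycles")
    return 100.0 * float(a.mean())


def min_recovery_interval(
    epoch_active: Sequence[Sequence[bool]], rests_s: Sequence[float] | None
) -> float | None:
    """Shortest rest that restored activity in a defined-interval trial.

    ``epoch_active`` holds the activity flags of the retained cycles of each
    epoch, in order; ``rests_s`` the rest durations *after* each epoch (the
    final entry is ignored).  An epoch counts as *resumed* when it contains
    at least one active cycle while the preceding epoch ended inactive (its
    final three retained cycles all inactive).  Returns the smallest
    preceding rest over all resumed epochs; 0 when no epoch ever loses
    activity; ``None`` when activity is lost and never resumes.
    """
    groups = [np.asarray(g, dtype=bool) for g in epoch_active]
    if len(groups) < 2:
        raise ProtocolError("interval protocol needs at least 2 epochs")
    if rests_s is None or len(rests_s) < len(groups) - 1:
        raise ProtocolError("rest durations are undefined for this protocol")

    def ended_inactive(g: np.ndarray) -> bool:
        tail = g[-3:] if len(g) >= 3 else g
        return len(tail) > 0 and not tail.any()

    lost = [ended_inactive(g) for g in groups[:-1]]
    if not any(lost):
        return 0.0
    resumed_rests = [
        float(rests_s[e - 1])
        for e in range(1, len(groups))
        if lost[e - 1] and groups[e].any()
    ]
    return min(resumed_rests) if resumed_rests else None


def summarize_trial(
    cycles: pd.DataFrame,
    rests_s: Sequence[float] | None = None,
    larva_id: str | None = None,
    genotype: str | None = None,
) -> TrialResult:
    """Temporal summary of one larva's per-cycle table.

    ``rests_s`` (rest after each epoch) enables the minimal-recovery-interval
    statistic; leave it ``None`` for single-epoch trials.  A half-time that
    is undefined for the trial (response never halves, or no initial
    response as in null phenotypes) is reported as ``None``.
    """
    retained = cycles[~cycles["excluded"]].reset_index(drop=True)
    if retained.empty:
        raise DegenerateTrialError("no retained cycles in trial")
    if larva_id is None:
        larva_id = str(retained["larva_id"].iloc[0])

    mid = retained["start_time_s"].to_numpy() + retained["duration_s"].to_numpy() / 2.0
    try:
        ht = half_time(mid, retained["normalized_integral_deg"].to_numpy())
    except (UndefinedHalfTimeError, InsufficientDataError):
        ht = None

    active = retained["active"].to_numpy(dtype=bool)
    cyc_dur = float(retained["duration_s"].median())
    pause_list = pauses(active, cyc_dur)

    mri: float | None = None
    n_epochs = int(cycles["epoch"].nunique())
    if rests_s is not None and n_epochs >= 2:
        # Epoch resumption is judged on every non-startle cycle: the first
        # cycle of an epoch is excluded from the metric analyses, but its
        # activity is still observable and is exactly where a recovered
        # response reappears.
        observable = cycles[cycles["exclusion_reason"] != "startle"]
        groups = [
            g["active"].to_numpy(dtype=bool)
            for _, g in observable.groupby("epoch", sort=True)
        ]
        mri = min_recovery_interval(groups, rests_s)

    return TrialResult(
        larva_id=larva_id,
        genotype=genotype,
        per_cycle=retained,
        half_time_s=ht,
        pct_active=pct_active(active),
        pauses_s=pause_list,
        min_recovery_interval_s=mri,
        n_retained=len(retained),
        n_excluded_startle=int((cycles["exclusion_reason"] == "startle").sum()),
    )
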