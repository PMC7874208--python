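"""Cycle segmentation and per-cycle VSR metrics.

The evoked response is quantified on the *difference signal*: the absolute
deviation of the tail angle from its 5-frame rolling median.  The rolling
median tracks the slow, platform-induced sway of the tail, so what remains
is the stimulus-evoked movement.  Cycles are delimited by black marker
frames; the first and last (complete or partial) cycle of each recording
epoch are excluded, as are cycles containing a startle excursion (>45°).

Per retained cycle three metrics are reported, all in the paper-standard
form: the maximum of the difference signal (degrees), its per-frame mean
("normalized integral", degrees — duration-invariant so partial cycles are
comparable), and the percentage of frames strictly above the activity
threshold (default 5°).  A cycle is *active* when its maximum difference
exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateCycleError, SegmentationError
from .synth import TailTrace

__all__ = [
    "Cycle",
    "CycleMetrics",
    "DEFAULT_THRESHOLD_DEG",
    "STARTLE_THRESHOLD_DEG",
    "rolling_median",
    "difference_signal",
    "segment_cycles",
    "flag_startles",
    "cycle_metrics",
    "analyze_trace",
]

DEFAULT_THRESHOLD_DEG = 5.0
STARTLE_THRESHOLD_DEG = 45.0
DEFAULT_WINDOW = 5

EXCLUSION_REASONS = ("first", "last_or_partial", "startle", "none")


@dataclass
class Cycle:
    """One black-frame-delimited stimulus cycle, half-open span [start, end)."""

    index: int
    start: int
    end: int
    epoch: int = 0
    excluded: bool = False
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("cycle span must be non-empty")
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValueError("excluded flag inconsistent with exclusion_reason")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def n_frames(self) -> int:
        return self.end - self.start


@dataclass
class CycleMetrics:
    """The per-cycle metric set computed from the difference signal."""

    max_tail_angle: float
    normalized_integral: float
    pct_above_threshold: float
    active: bool


def rolling_median(angles: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered windowed median; the window shrinks symmetrically at the edges.

    At index ``i`` the window is ``angles[i-h : i+h+1]`` with
    ``h = min(window // 2, i, n - 1 - i)``, so the output has the same length
    as the input and the first/last samples are their own medians.
    """
    a = np.asarray(angles, dtype=float)
    n = len(a)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    if window > n:
        raise ValueError(f"window ({window}) exceeds series length ({n})")
    h = window // 2
    out = np.empty(n)
    if n >= window:
        sw = np.lib.stride_tricks.sliding_window_view(a, window)
        out[h : n - h] = np.median(sw, axis=1)
    for i in range(h):
        k = min(i, n - 1 - i)
        out[i] = np.median(a[i - k : i + k + 1])
        j = n - 1 - i
        k = min(j, n - 1 - j)
        out[j] = np.median(a[j - k : j + k + 1])
    return out


def difference_signal(
    angles: np.ndarray,
    window: int = DEFAULT_WINDOW,
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Absolute deviation of the tail angle from its rolling median.

    Invalid frames (black markers) carry the value 0 so they never
    contribute to any metric.
    """
    a = np.asarray(angles, dtype=float)
    d = np.abs(a - rolling_median(a, window))
    if valid is not None:
        d = np.where(np.asarray(valid, dtype=bool), d, 0.0)
    return d


def _segment_epoch(blacks: np.ndarray, epoch_end: int) -> list[tuple[int, int]]:
    spans = [(int(blacks[i]), int(blacks[i + 1])) for i in range(len(blacks) - 1)]
    # A lone trailing black frame is not a cycle; anything longer forms the
    # (typically partial) final cycle, which is excluded below anyway.
    last_black = int(blacks[-1])
    if epoch_end - last_black > 1:
        spans.append((last_black, epoch_end))
    return spans


def segment_cycles(trace: TailTrace) -> list[Cycle]:
    """Segment a trace into cycles between consecutive black frames.

    Segmentation runs per recording epoch; in each epoch the first cycle and
    the final (complete-or-partial) cycle are excluded, reproducing the
    practice of dropping the first and last cycles of every recording.
    Cycle indices are global and sequential across epochs.
    """
    if len(trace.black_frames) < 2:
        raise SegmentationError(
            f"need at least 2 black frames to segment, got {len(trace.black_frames)}"
        )
    cycles: list[Cycle] = []
    idx = 0
    for e, ep in enumerate(trace.epoch_spans()):
        blk = trace.black_frames[
            (trace.black_frames >= ep.start) & (trace.black_frames < ep.stop)
        ]
        if len(blk) < 2:
            continue
        spans = _segment_epoch(blk, ep.stop)
        for j, (s, en) in enumerate(spans):
            if j == 0:
                reason = "first"
            elif j == len(spans) - 1:
                reason = "last_or_partial"
            else:
                reason = "none"
            cycles.append(
                Cycle(
                    index=idx,
                    start=s,
                    end=en,
                    epoch=e,
                    excluded=reason != "none",
                    exclusion_reason=reason,
                )
            )
            idx += 1
    if not cycles:
        raise SegmentationError("no epoch contained 2 black frames")
    return cycles


def flag_startles(
    trace: TailTrace,
    cycles: list[Cycle],
    startle_threshold: float = STARTLE_THRESHOLD_DEG,
    window: int = DEFAULT_WINDOW,
) -> list[Cycle]:
    """Exclude retained cycles whose difference signal exceeds the startle bound.

    Automates the manual rule of discarding cycles that contain a startle
    (tail movement larger than 45°).  Returns the same cycle list with
    exclusions updated in place.
    """
    diff = difference_signal(trace.angles, window, trace.valid)
    for c in cycles:
        if c.excluded:
            continue
        if np.max(diff[c.start : c.end]) > startle_threshold:
            c.excluded = True
            c.exclusion_reason = "startle"
    return cycles


def cycle_metrics(
    trace: TailTrace,
    cycle: Cycle,
    threshold: float = DEFAULT_THRESHOLD_DEG,
    window: int = DEFAULT_WINDOW,
) -> CycleMetrics:
    """Metric set of one cycle, computed over its valid frames.

    Frames exactly at the threshold count as *not* above it (strict
    inequality), for both the percentage metric and the activity flag.
    """
    valid = trace.valid[cycle.start : cycle.end]
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DegenerateCycleError(f"cycle {cycle.index} has no valid frames")
    diff = difference_signal(trace.angles, window, trace.valid)[cycle.start : cycle.end]
    d = diff[valid]
    mx = float(np.max(d))
    integral = float(np.sum(d) / n_valid)
    pct = 100.0 * float(np.count_nonzero(d > threshold)) / n_valid
    return CycleMetrics(
        max_tail_angle=mx,
        normalized_integral=integral,
        pct_above_threshold=pct,
        active=mx > threshold,
    )


def analyze_trace(
    trace: TailTrace,
    threshold: float = DEFAULT_THRESHOLD_DEG,
    window: int = DEFAULT_WINDOW,
    startle_threshold: float = STARTLE_THRESHOLD_DEG,
    larva_id: str = "larva",
) -> pd.DataFrame:
    """Full per-cycle table of a trace: segmentation, exclusions, metrics.

    Metrics are reported for every cycle except startle-excluded ones
    (whose difference signal is artifact-dominated and kept NaN, with
    ``active`` False).  First/last cycles keep their metrics so that epoch
    activity is observable, but stay flagged excluded and enter no group
    analysis.  Each row carries the cycle's absolute start time and
    duration in seconds, which the temporal statistics need.
    """
    cycles = flag_startles(
        trace, segment_cycles(trace), startle_threshold, window
    )
    times = trace.times()
    rows = []
    for c in cycles:
        if c.exclusion_reason == "startle":
            m = CycleMetrics(np.nan, np.nan, np.nan, False)
        else:
            m = cycle_metrics(trace, c, threshold, window)
        rows.append(
            {
                "larva_id": larva_id,
                "cycle_index": c.index,
                "epoch": c.epoch,
                "start_time_s": float(times[c.start]),
                "duration_s": c.n_frames() / trace.fps,
                "excluded": c.excluded,
                "exclusion_reason": c.exclusion_reason,
                "max_tail_angle_deg": m.max_tail_angle,
                "normalized_integral_deg": m.normalized_integral,
                "pct_above_threshold": m.pct_above_threshold,
                "active": m.active,
            }
        )
    return pd.DataFrame(rows)
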