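"""Recover the tail angle and marker schedule from a frame sequence.

The tracker mirrors the measurement definition used at the rig: segment the
bright larva body, skeletonize it, walk the skeleton from the wide
(swim-bladder) end to the tail tip, resample 10 evenly spaced midline
points, and report the signed angle between the body axis and the chord
from the swim-bladder centre to the tail tip.  The body axis is estimated
once, from the first trackable frame, and reused for the whole recording.

Individual untrackable frames (black markers, segmentation failures) are
carried as invalid and filled by linear interpolation so cycle frame counts
stay fixed; a recording where more than 20% of illuminated frames fail is
rejected outright.
"""

from __future__ import annotations

from collections import deque
from pathlib import Path
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.measure import label
from skimage.morphology import skeletonize

from .errors import TrackingFailure, UnusableRecordingError
from .synth import EpochSpan, StimulusProtocol, TailTrace

__all__ = [
    "Midline",
    "detect_black_frames",
    "extract_midline",
    "compute_tail_angle",
    "track_video",
    "read_frames",
]

N_MIDLINE_POINTS = 10


@dataclass
class Midline:
    """Ten ordered midline coordinates from swim-bladder end to tail tip.

    Coordinates are (x, y) = (column, row) pixels.  ``body_axis`` is the
    unit head→tail direction of the trunk; it is filled in by
    :func:`track_video` (estimated from the first valid frame) or can be
    supplied directly.
    """

    points: np.ndarray  # (10, 2)
    bladder_center: np.ndarray
    tip: np.ndarray
    body_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_MIDLINE_POINTS, 2):
            raise ValueError(f"midline must have exactly {N_MIDLINE_POINTS} points")
        self.bladder_center = np.asarray(self.bladder_center, dtype=float)
        self.tip = np.asarray(self.tip, dtype=float)
        if self.body_axis is not None:
            self.body_axis = np.asarray(self.body_axis, dtype=float)


def detect_black_frames(
    frames: Sequence[np.ndarray] | np.ndarray, intensity_fraction: float = 0.1
) -> np.ndarray:
    """Indices of marker frames: mean intensity below a fraction of the median.

    The threshold adapts to the recording (``intensity_fraction`` times the
    median per-frame mean), so absolute illumination level does not matter.
    """
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    if not 0 < intensity_fraction < 1:
        raise ValueError("intensity_fraction must be in (0, 1)")
    means = np.array([np.mean(f) for f in frames], dtype=float)
    return np.flatnonzero(means < intensity_fraction * np.median(means))


def _skeleton_longest_path(skel: np.ndarray) -> list[tuple[int, int]]:
    """Longest geodesic path through a pixel skeleton (8-connectivity)."""
    pixels = set(zip(*np.nonzero(skel)))
    if not pixels:
        raise TrackingFailure("empty skeleton")
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]

    def neighbors(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in offsets if (p[0] + dr, p[1] + dc) in pixels]

    def bfs(src):
        dist = {src: 0}
        prev = {}
        q = deque([src])
        far = src
        while q:
            p = q.popleft()
            if dist[p] > dist[far]:
                far = p
            for nb in neighbors(p):
                if nb not in dist:
                    dist[nb] = dist[p] + 1
                    prev[nb] = p
                    q.append(nb)
        return far, prev

    start = next(iter(pixels))
    e1, _ = bfs(start)
    e2, prev = bfs(e1)
    path = [e2]
    while path[-1] != e1:
        path.append(prev[path[-1]])
    return path  # from e2 to e1; orientation fixed later


def extract_midline(
    frame: np.ndarray,
    intensity_threshold: float | None = None,
    min_peak_intensity: float = 32.0,
) -> Midline:
    """Extract the 10-point tail midline from one grayscale frame.

    The body is segmented at ``intensity_threshold`` (default: 40% of the
    frame's peak intensity), the largest connected region is skeletonized,
    and the longest skeleton path is oriented so it starts at the wide end.
    The swim-bladder centre is taken as the widest point along that path
    (the maximum of the distance transform) and the skeleton tip is
    extended by the local body half-width to undo skeleton retraction.

    Raises
    ------
    TrackingFailure
        For frames with no body region (black frames), a region touching
        three or more image borders, or a degenerate skeleton.
    """
    frame = np.asarray(frame, dtype=float)
    peak = frame.max()
    if peak < min_peak_intensity:
        raise TrackingFailure("no bright body region (black or empty frame)")
    thr = intensity_threshold if intensity_threshold is not None else 0.4 * peak
    mask = frame >= thr
    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        raise TrackingFailure("no region above intensity threshold")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    body = labels == np.argmax(sizes)
    borders = (
        int(body[0, :].any())
        + int(body[-1, :].any())
        + int(body[:, 0].any())
        + int(body[:, -1].any())
    )
    if borders >= 3:
        raise TrackingFailure("body region touches 3 or more image borders")

    skel = skeletonize(body)
    path_rc = _skeleton_longest_path(skel)
    if len(path_rc) < N_MIDLINE_POINTS:
        raise TrackingFailure("skeleton too short to resample")
    dt = distance_transform_edt(body)
    widths = np.array([dt[r, c] for r, c in path_rc])
    k = min(5, len(path_rc) // 2)
    if widths[:k].mean() < widths[-k:].mean():
        path_rc = path_rc[::-1]
        widths = widths[::-1]

    pts = np.array([(c, r) for r, c in path_rc], dtype=float)  # (x, y)
    # Bladder centre: the widest point, searched in the proximal half.
    bladder_i = int(np.argmax(widths[: max(1, len(widths) // 2)]))
    pts = pts[bladder_i:]
    if len(pts) < 3:
        raise TrackingFailure("tail segment too short after bladder localization")
    # Undo skeleton retraction at the tip.
    tail_dir = pts[-1] - pts[-min(6, len(pts) - 1)]
    norm = np.linalg.norm(tail_dir)
    if norm > 0:
        tip_width = widths[bladder_i:][-1]
        pts = np.vstack([pts, pts[-1] + tail_dir / norm * tip_width])

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    if arclen[-1] <= 0:
        raise TrackingFailure("degenerate midline")
    targets = np.linspace(0.0, arclen[-1], N_MIDLINE_POINTS)
    resampled = np.column_stack(
        [np.interp(targets, arclen, pts[:, 0]), np.interp(targets, arclen, pts[:, 1])]
    )
    return Midline(
        points=resampled, bladder_center=resampled[0].copy(), tip=resampled[-1].copy()
    )


def compute_tail_angle(midline: Midline, body_axis: np.ndarray | None = None) -> float:
    """Signed tail angle in degrees, in (−180, 180].

    The angle between the body axis and the chord from the swim-bladder
    centre to the tail tip.  Positive means deflection toward the axis's
    left-hand perpendicular, consistently across frames.
    """
    axis = body_axis if body_axis is not None else midline.body_axis
    if axis is None:
        raise ValueError("no body axis available; supply body_axis")
    axis = np.asarray(axis, dtype=float)
    chord = midline.tip - midline.bladder_center
    if np.linalg.norm(chord) == 0:
        raise ValueError("zero-length chord: tail angle undefined")
    ang = np.degrees(
        np.arctan2(axis[0] * chord[1] - axis[1] * chord[0], axis @ chord)
    )
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def _estimate_body_axis(midline: Midline) -> np.ndarray:
    """Trunk direction from the proximal midline points of a reference frame."""
    v = midline.points[2] - midline.points[0]
    n = np.linalg.norm(v)
    if n == 0:
        raise TrackingFailure("cannot estimate body axis from degenerate midline")
    return v / n


def track_video(
    frames: Sequence[np.ndarray] | np.ndarray,
    protocol: StimulusProtocol | None = None,
    fps: float | None = None,
    intensity_fraction: float = 0.1,
    body_axis: np.ndarray | None = None,
    max_failure_fraction: float = 0.2,
    keep_midlines: bool = False,
) -> TailTrace:
    """Track a whole recording into a :class:`TailTrace`.

    Black frames are detected first; every other frame goes through midline
    extraction and the tail-angle computation.  Tracking failures and black
    frames are marked invalid and their angles filled by linear
    interpolation from the nearest valid neighbours.

    Raises
    ------
    UnusableRecordingError
        If more than ``max_failure_fraction`` of illuminated frames fail.
    """
    n = len(frames)
    if n == 0:
        raise ValueError("empty frame sequence")
    blacks = detect_black_frames(frames, intensity_fraction)
    black_set = set(int(b) for b in blacks)

    angles = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    midlines: list[Midline | None] = [None] * n
    axis = None if body_axis is None else np.asarray(body_axis, dtype=float)
    failures = 0
    for i in range(n):
        if i in black_set:
            continue
        try:
            ml = extract_midline(frames[i])
        except TrackingFailure:
            failures += 1
            continue
        if axis is None:
            axis = _estimate_body_axis(ml)
        ml.body_axis = axis
        angles[i] = compute_tail_angle(ml)
        valid[i] = True
        if keep_midlines:
            midlines[i] = ml

    n_lit = n - len(black_set)
    if n_lit == 0 or axis is None or not valid.any():
        raise UnusableRecordingError("no trackable frames in recording")
    if failures / n_lit > max_failure_fraction:
        raise UnusableRecordingError(
            f"{failures}/{n_lit} illuminated frames failed tracking "
            f"(> {max_failure_fraction:.0%}): unusable recording"
        )

    idx = np.arange(n)
    angles[~valid] = np.interp(idx[~valid], idx[valid], angles[valid])

    if fps is None:
        fps = protocol.fps if protocol is not None else 30.0
    meta: dict = {"body_axis": axis, "n_tracking_failures": failures}
    if keep_midlines:
        meta["midlines"] = midlines
    epochs = [EpochSpan(0, n, 0.0, 0.0)]
    return TailTrace(
        angles=angles,
        fps=float(fps),
        black_frames=np.asarray(sorted(black_set), dtype=int),
        valid=valid,
        meta=meta,
        epochs=epochs,
    )


def read_frames(path: str | Path) -> np.ndarray:
    """Load a recording from a directory of numbered PNGs or an AVI file.

    PNG directories are read in lexicographic order (which equals temporal
    order for zero-padded names).  AVI decoding needs an ffmpeg-capable
    imageio plugin; a clear error is raised when none is available.
    """
    import imageio.v3 as iio

    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames found in {p}")
        return np.stack([iio.imread(f) for f in files])
    if not p.exists():
        raise FileNotFoundError(f"no such video or frame directory: {p}")
    try:
        return np.asarray(iio.imread(p, index=None))
    except Exception as exc:  # pragma: no cover - depends on plugin availability
        raise RuntimeError(
            f"could not decode {p}; for AVI input an ffmpeg-capable imageio "
            "plugin is required — alternatively supply a PNG frame directory"
        ) from exc
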