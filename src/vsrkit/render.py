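"""Render synthetic camera frames from a tail-angle trace.

Produces the kind of image the VSR rig records: a bright larva on a dark
background, head embedded at a fixed position, tail free.  The tail is drawn
as a smooth quadratic arc whose chord from the swim-bladder centre to the
tail tip makes the trace's angle α with the body axis, so a tracker that
recovers that chord recovers α by construction.  Black marker frames are
rendered as all-zero images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import RenderError
from .synth import TailTrace

__all__ = ["LarvaGeometry", "render_frames", "write_frames"]


@dataclass(frozen=True)
class LarvaGeometry:
    """Where and how the larva is drawn, in pixel units.

    ``bladder_xy`` uses (x, y) = (column, row).  ``axis_deg`` is the body-axis
    direction (head→tail) measured like the tail angle itself, so a rendered
    frame plus its ``axis_deg`` form a self-consistent ground truth.
    """

    bladder_xy: tuple[float, float] = (60.0, 100.0)
    axis_deg: float = 0.0
    chord_px: float = 70.0
    head_radius: float = 12.0
    tail_base_halfwidth: float = 5.0
    tail_tip_halfwidth: float = 1.3
    bend: float = 0.5  # control-point distance along the axis, as a chord fraction
    body_intensity: int = 220
    background: int = 8
    blur_sigma: float = 1.0


def _tail_curve(geom: LarvaGeometry, angle_deg: float, n_samples: int = 120):
    ax = math.radians(geom.axis_deg)
    u = np.array([math.cos(ax), math.sin(ax)])
    p = np.array([-math.sin(ax), math.cos(ax)])
    b = np.array(geom.bladder_xy, dtype=float)
    a = math.radians(angle_deg)
    tip = b + geom.chord_px * (math.cos(a) * u + math.sin(a) * p)
    ctrl = b + geom.bend * geom.chord_px * u
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    pts = (1 - t) ** 2 * b + 2 * t * (1 - t) * ctrl + t**2 * tip
    radii = geom.tail_base_halfwidth * (1 - t[:, 0]) + geom.tail_tip_halfwidth * t[:, 0]
    return pts, radii


def _render_one(
    angle_deg: float, shape: tuple[int, int], geom: LarvaGeometry
) -> np.ndarray:
    h, w = shape
    pts, radii = _tail_curve(geom, angle_deg)
    margin = 2.0
    lo = pts - (radii[:, None] + margin)
    hi = pts + (radii[:, None] + margin)
    if lo.min() < 0 or hi[:, 0].max() >= w or hi[:, 1].max() >= h:
        raise RenderError(
            f"tail at angle {angle_deg:.1f}° leaves the {w}x{h} image; "
            "enlarge the image or shorten the tail"
        )
    canvas = np.full(shape, float(geom.background))
    yy, xx = np.mgrid[0:h, 0:w]
    bx, by = geom.bladder_xy
    canvas[(xx - bx) ** 2 + (yy - by) ** 2 <= geom.head_radius**2] = geom.body_intensity
    # Stamp disks along the curve; loop is fine at this resolution.
    for (x, y), r in zip(pts, radii):
        x0, x1 = int(x - r - 1), int(x + r + 2)
        y0, y1 = int(y - r - 1), int(y + r + 2)
        sub_y, sub_x = np.mgrid[y0:y1, x0:x1]
        mask = (sub_x - x) ** 2 + (sub_y - y) ** 2 <= r**2
        canvas[y0:y1, x0:x1][mask] = geom.body_intensity
    if geom.blur_sigma > 0:
        canvas = gaussian_filter(canvas, geom.blur_sigma)
    return np.clip(canvas, 0, 255).astype(np.uint8)


def render_frames(
    trace: TailTrace,
    image_size: tuple[int, int] = (200, 200),
    geometry: LarvaGeometry | None = None,
) -> np.ndarray:
    """Render a ``(n_frames, height, width)`` uint8 stack from a trace.

    Frames flagged invalid in the trace (the black markers) are rendered as
    all-zero images, exactly as the rig records them.
    """
    geom = geometry or LarvaGeometry()
    frames = np.zeros((trace.n_frames, *image_size), dtype=np.uint8)
    # Render distinct angles once; traces quantized by noise rarely repeat,
    # but black frames are skipped which is the dominant saving.
    for i in range(trace.n_frames):
        if not trace.valid[i]:
            continue
        frames[i] = _render_one(float(trace.angles[i]), image_size, geom)
    return frames


def write_frames(frames: np.ndarray, out_dir: str | Path) -> list[Path]:
    """Write a frame stack as zero-padded numbered grayscale PNGs."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(len(frames) - 1)))
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"frame_{i:0{width}d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths
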