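"""M-mode kymograph construction from image stacks.

A kymograph is a 2-D image with one spatial scan line per time point: rows are
positions along a 1-pixel-wide line drawn perpendicularly through the heart
walls, columns are frames.  This module builds kymographs from multi-page
image stacks along a user-supplied or automatically suggested line.

Coordinates are 0-based ``(row, column)`` pixel coordinates of a stack frame.
Samples along the line are taken at 1-pixel steps with bilinear interpolation
(nearest-neighbour available for bit-compatibility checks against integer
pipelines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError, NoMotionError

__all__ = ["KymographImage", "LineSpec", "build_kymograph", "suggest_line"]


@dataclass
class LineSpec:
    """A 1-pixel-wide scan line between two points of a stack frame.

    ``start`` and ``end`` are ``(row, column)`` pixel coordinates; sampling
    proceeds from ``start`` towards ``end`` in unit-pixel steps.
    """

    start: tuple[float, float]
    end: tuple[float, float]

    def __post_init__(self) -> None:
        if np.allclose(self.start, self.end):
            raise ValueError("line endpoints must be distinct")

    @property
    def length(self) -> float:
        """Euclidean length in pixels."""
        return float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))

    @property
    def n_samples(self) -> int:
        """Number of unit-step samples: floor(length) + 1 (endpoints included)."""
        return int(np.floor(self.length + 1e-9)) + 1

    def sample_coordinates(self) -> np.ndarray:
        """(2, n_samples) array of (row, col) coordinates at 1-pixel spacing."""
        n = self.n_samples
        u = np.arange(n, dtype=float)
        d = np.asarray(self.end, float) - np.asarray(self.start, float)
        unit = d / self.length
        coords = np.asarray(self.start, float)[:, None] + unit[:, None] * u[None, :]
        return coords


@dataclass
class KymographImage:
    """Space x time intensity map of heart-wall motion.

    ``intensity`` has shape ``(n_positions, n_frames)``: one column per source
    frame, rows ordered along the scan line.  ``pixel_size`` is micrometres
    per pixel along the line, ``frame_rate`` frames per second.
    """

    intensity: np.ndarray
    pixel_size: float
    frame_rate: float
    line_spec: LineSpec | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph intensity must be 2-D (space x time)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("kymograph intensity must be finite everywhere")
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_positions(self) -> int:
        return self.intensity.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (frame count / frame rate)."""
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Time of each column in seconds; frame k starts at k / frame_rate."""
        return np.arange(self.n_frames) / self.frame_rate


def build_kymograph(
    stack: np.ndarray,
    line: LineSpec,
    *,
    pixel_size: float = 1.0,
    frame_rate: float = 100.0,
    interpolation: str = "bilinear",
) -> KymographImage:
    """Build an M-mode kymograph by sampling each frame along ``line``.

    Parameters
    ----------
    stack
        ``(n_frames, height, width)`` image stack.
    line
        Scan line through the heart walls; must lie inside the frame.
    interpolation
        ``"bilinear"`` (default) or ``"nearest"``.

    Returns
    -------
    KymographImage with one column per frame and ``floor(line length) + 1``
    rows.  Column count always equals the input frame count; there is no
    temporal resampling.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frames, height, width) array")
    n_frames, height, width = stack.shape

    coords = line.sample_coordinates()
    r, c = coords
    inside = (r >= -0.5) & (r <= height - 0.5) & (c >= -0.5) & (c <= width - 0.5)
    if not np.all(inside):
        lo, hi = np.flatnonzero(inside)[[0, -1]] if inside.any() else (0, -1)
        raise GeometryError(
            f"scan line leaves the {height}x{width} frame; only samples "
            f"{lo}..{hi} of {coords.shape[1]} fall inside"
        )

    order = {"bilinear": 1, "nearest": 0}[interpolation]
    n = coords.shape[1]
    frame_idx = np.repeat(np.arange(n_frames, dtype=float), n)
    rows = np.tile(r, n_frames)
    cols = np.tile(c, n_frames)
    sampled = ndimage.map_coordinates(
        stack, np.stack([frame_idx, rows, cols]), order=order, mode="nearest"
    )
    intensity = sampled.reshape(n_frames, n).T  # rows = space, cols = frames

    return KymographImage(
        intensity=intensity,
        pixel_size=pixel_size,
        frame_rate=frame_rate,
        line_spec=line,
        metadata={"interpolation": interpolation},
    )


def suggest_line(
    stack: np.ndarray,
    *,
    variance_threshold: float = 1e-10,
    margin: float = 2.0,
) -> LineSpec:
    """Suggest a scan line through the region of maximal temporal variance.

    The heart walls are the only structures that move, so the per-pixel
    temporal variance map highlights the swept band.  The returned line passes
    through the variance-weighted centroid, oriented along the principal axis
    of spatial variation of the variance map (perpendicular to the wall
    bands), and spans the high-variance region plus ``margin`` times its
    extent on each side, clipped to the frame.

    Deterministic for a fixed stack.  Raises :class:`NoMotionError` when the
    maximal temporal variance falls below ``variance_threshold`` relative to
    the squared dynamic range.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must contain at least two frames")
    var = stack.var(axis=0)
    dyn = np.ptp(stack)
    if dyn == 0 or var.max() <= variance_threshold * dyn**2:
        raise NoMotionError("no motion detected: temporal variance below threshold")

    # weight by variance above half-max to localise the swept band
    w = np.clip(var - 0.5 * var.max(), 0, None)
    total = w.sum()
    rr, cc = np.mgrid[0 : var.shape[0], 0 : var.shape[1]]
    r0 = (w * rr).sum() / total
    c0 = (w * cc).sum() / total
    # scan direction from the structure tensor of the variance map: the wall
    # bands are ridges, so the dominant gradient direction crosses them
    sm = ndimage.gaussian_filter(var, 1.5)
    gr, gc = np.gradient(sm)
    tensor = np.array(
        [[(gr * gr).sum(), (gr * gc).sum()], [(gr * gc).sum(), (gc * gc).sum()]]
    )
    evals, evecs = np.linalg.eigh(tensor)
    if evals[1] > 1e-12 * max(sm.max(), 1e-300) ** 2:
        direction = evecs[:, 1]  # dominant gradient direction
    else:
        direction = np.array([1.0, 0.0])
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction

    # half-extent of motion along the scan direction, padded by `margin`
    proj = (rr - r0) * direction[0] + (cc - c0) * direction[1]
    mask = w > 0
    half = float(np.abs(proj[mask]).max()) if mask.any() else 1.0
    half = (half + 1.0) * (1.0 + margin)

    height, width = var.shape
    start = np.array([r0, c0]) - half * direction
    end = np.array([r0, c0]) + half * direction
    # clip both endpoints to the frame along the line
    for p in (start, end):
        p[0] = np.clip(p[0], 0, height - 1)
        p[1] = np.clip(p[1], 0, width - 1)
    return LineSpec(start=(float(start[0]), float(start[1])), end=(float(end[0]), float(end[1])))
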