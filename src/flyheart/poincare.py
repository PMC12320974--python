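"""Poincare analysis of beat-to-beat variability.

Each inter-contraction interval ``n`` is plotted against the next interval
``n+1``; the scatter is summarised by a confidence ellipse at level 0.99 (the
chi-square(2 df) population-quantile ellipse on the sample mean and sample
covariance), whose area quantifies rhythm variability.  Paired recordings are
compared by the percent change of ellipse area after tachypacing relative to
before, alongside the absolute areas.

Area of the level-``q`` ellipse of a covariance matrix S is
``pi * q * sqrt(det S)`` with ``q = chi2.ppf(level, df=2) = -2 ln(1-level)``.
Areas are reported in ms^2 by default (intervals are fractions of a second,
so s^2 areas are unreadably small).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .beats import BeatIntervalSeries
from .exceptions import DegenerateDataError, TooFewBeatsError

__all__ = [
    "PoincarePairs",
    "PoincareEllipse",
    "lag_pairs",
    "fit_ellipse",
    "ellipse_delta",
    "plot_poincare",
]

_DEGENERATE_DET = 1e-300


@dataclass
class PoincarePairs:
    """Lagged interval pairs (I_n, I_{n+1}) in seconds, order preserved."""

    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if np.any(self.points <= 0):
            raise ValueError("intervals must be positive")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class PoincareEllipse:
    """Confidence ellipse of the lagged-interval cloud.

    ``area`` is in seconds^2 (``area_ms2`` converts); ``degenerate`` flags a
    singular covariance (collinear or identical points), in which case the
    area is 0.
    """

    center: np.ndarray
    covariance: np.ndarray
    level: float
    quantile: float
    area: float
    degenerate: bool = False
    n: int = 0

    @property
    def area_ms2(self) -> float:
        return self.area * 1e6

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        if self.degenerate:
            raise DegenerateDataError("degenerate ellipse has no interior")
        d = np.asarray(points, float) - self.center
        md2 = np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.covariance), d)
        return md2 <= self.quantile


def lag_pairs(series: BeatIntervalSeries) -> PoincarePairs:
    """Pair each interval with its successor: points[i] = (iv[i], iv[i+1])."""
    iv = series.intervals
    if iv.size < 2:
        raise TooFewBeatsError("Poincare pairs need at least 2 intervals", series.n_events)
    return PoincarePairs(points=np.column_stack([iv[:-1], iv[1:]]))


def fit_ellipse(pairs: PoincarePairs, level: float = 0.99) -> PoincareEllipse:
    """Fit the chi-square(2 df) quantile ellipse to the lagged pairs.

    Center = sample mean, covariance = sample covariance (n-1 denominator),
    quantile = chi-square 2-df inverse CDF at ``level`` (closed form
    ``-2 ln(1-level)``).  Collinear or identical points give a degenerate
    ellipse with area 0 and a flag, not an exception.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if pairs.n < 3:
        raise TooFewBeatsError("ellipse fit needs at least 3 points", pairs.n)
    center = pairs.points.mean(axis=0)
    cov = np.cov(pairs.points, rowvar=False, ddof=1)
    quantile = float(chi2.ppf(level, df=2))  # == -2 ln(1 - level)
    det = float(np.linalg.det(cov))
    degenerate = det <= _DEGENERATE_DET
    area = 0.0 if degenerate else float(np.pi * quantile * np.sqrt(det))
    return PoincareEllipse(
        center=center,
        covariance=cov,
        level=level,
        quantile=quantile,
        area=area,
        degenerate=degenerate,
        n=pairs.n,
    )


def ellipse_delta(btp: PoincareEllipse, atp: PoincareEllipse) -> float:
    """Percent change of ellipse area after pacing: (ATP - BTP)/BTP * 100."""
    if btp.degenerate or btp.area <= 0:
        raise DegenerateDataError(
            "BTP ellipse is degenerate; report absolute areas instead of a percent change"
        )
    return (atp.area - btp.area) / btp.area * 100.0


def _ellipse_outline(e: PoincareEllipse, n: int = 200) -> np.ndarray:
    """(n, 2) polyline tracing the ellipse boundary."""
    evals, evecs = np.linalg.eigh(e.covariance)
    theta = np.linspace(0, 2 * np.pi, n)
    circ = np.column_stack([np.cos(theta), np.sin(theta)])
    axes = np.sqrt(np.clip(evals, 0, None) * e.quantile)
    return e.center + circ * axes @ evecs.T


def plot_poincare(
    pairs_btp: PoincarePairs,
    ellipse_btp: PoincareEllipse,
    pairs_atp: PoincarePairs | None = None,
    ellipse_atp: PoincareEllipse | None = None,
    *,
    path: str | None = None,
    title: str | None = None,
):
    """Superimposed Poincare scatter with BTP (solid) and ATP (dashed) ellipses.

    Degenerate ellipses are omitted with a note on the axes.  Returns the
    matplotlib figure; writes it to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for pairs, ellipse, label, color, ls in (
        (pairs_btp, ellipse_btp, "BTP", "k", "-"),
        (pairs_atp, ellipse_atp, "ATP", "tab:red", "--"),
    ):
        if pairs is None:
            continue
        ax.plot(*(pairs.points.T * 1000), ".", ms=4, alpha=0.6, color=color, label=label)
        if ellipse is not None:
            if ellipse.degenerate:
                ax.annotate(f"{label}: degenerate ellipse", (0.02, 0.95 if label == "BTP" else 0.90),
                            xycoords="axes fraction", fontsize=8)
            else:
                outline = _ellipse_outline(ellipse) * 1000
                ax.plot(outline[:, 0], outline[:, 1], ls, color=color, lw=1.5)
    ax.set_xlabel("interval n (ms)")
    ax.set_ylabel("interval n+1 (ms)")
    ax.set_aspect("equal", adjustable="datalim")
    ax.legend(loc="lower right", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
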