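"""Heart-function endpoints: heart rate, arrhythmicity index, fractional shortening.

Definitions
-----------
HR
    Beats per minute, ``60 / mean(inter-contraction interval in seconds)``.
    Using the mean interval rather than event count / duration is robust to
    partial beats at the recording edges; ``strategy="count"`` gives the
    alternative.
AI
    Arrhythmicity index in arbitrary units: the dispersion of the inter-beat
    intervals normalised by a central interval value.  The default is the
    field-standard ``SD(intervals) / median(interval)``; ``sd_over_mean`` and
    plain ``sd`` are available as strategy switches.  Sample (n-1) standard
    deviation throughout.
FS
    Fractional shortening in percent, ``(DD - SD) / DD * 100`` with DD and SD
    the end-diastolic and end-systolic wall-to-wall diameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .beats import (
    BeatIntervalSeries,
    DiameterMeasurement,
    detect_contractions,
    extract_profile,
    measure_diameters,
)
from .exceptions import DegenerateDataError, FlyheartError, TooFewBeatsError
from .kymo import KymographImage

__all__ = [
    "CardiacMetrics",
    "MetricsDelta",
    "heart_rate",
    "arrhythmicity_index",
    "fractional_shortening",
    "compute_metrics",
    "metrics_delta",
]

logger = logging.getLogger(__name__)


@dataclass
class CardiacMetrics:
    """Per-recording endpoint bundle (one row of the metrics table)."""

    hr: float  # beats per minute
    ai: float  # arbitrary units
    fs: float  # percent
    dd: float  # end-diastolic diameter, micrometres
    sd: float  # end-systolic diameter, micrometres
    n_beats: int
    condition: str | None = None  # "BTP" or "ATP"


@dataclass
class MetricsDelta:
    """Paired ATP - BTP differences for one animal."""

    d_hr: float
    d_ai: float
    d_fs: float


def heart_rate(series: BeatIntervalSeries, strategy: str = "mean") -> float:
    """Heart rate in BPM from an interval series (needs >= 2 events)."""
    if series.n_events < 2:
        raise TooFewBeatsError("heart rate needs at least 2 events", series.n_events)
    if strategy == "mean":
        return 60.0 / float(np.mean(series.intervals))
    if strategy == "count":
        return 60.0 * series.n_events / series.duration
    raise ValueError(f"unknown HR strategy {strategy!r}")


def arrhythmicity_index(series: BeatIntervalSeries, strategy: str = "sd_over_median") -> float:
    """Arrhythmicity index (A.U.) from an interval series (needs >= 2 intervals)."""
    iv = series.intervals
    if iv.size < 2:
        raise TooFewBeatsError("AI needs at least 2 intervals (3 events)", series.n_events)
    sd = float(np.std(iv, ddof=1))
    if strategy == "sd_over_median":
        return sd / float(np.median(iv))
    if strategy == "sd_over_mean":
        return sd / float(np.mean(iv))
    if strategy == "sd":
        return sd
    raise ValueError(f"unknown AI strategy {strategy!r}")


def fractional_shortening(d: DiameterMeasurement) -> float:
    """Fractional shortening in percent: (DD - SD) / DD * 100."""
    dd, sd = d.diastolic_diameter, d.systolic_diameter
    if dd <= 0:
        raise DegenerateDataError("diastolic diameter must be positive")
    fs = (dd - sd) / dd * 100.0
    if sd > dd:
        logger.warning("systolic diameter %.3g exceeds diastolic %.3g: negative FS", sd, dd)
    return fs


def compute_metrics(
    kymo: KymographImage,
    *,
    condition: str | None = None,
    row: int | None = None,
    window: int = 5,
    row_strategy: str = "systolic",
    polarity: str = "minima",
    prominence_k: float = 4.0,
    refractory_s: float = 0.15,
    n_diameter_lines: int = 10,
    hr_strategy: str = "mean",
    ai_strategy: str = "sd_over_median",
) -> CardiacMetrics:
    """Full per-recording pipeline: profile -> events -> diameters -> formulas.

    Deterministic composition of :func:`~flyheart.beats.extract_profile`,
    :func:`~flyheart.beats.detect_contractions`,
    :func:`~flyheart.beats.measure_diameters` and the three endpoint
    formulas.  Stage failures propagate with the stage name attached.
    """
    try:
        trace = extract_profile(kymo, row, window=window, row_strategy=row_strategy)
    except FlyheartError as e:
        raise type(e)(f"[extract_profile] {e}") from e
    try:
        events = detect_contractions(
            trace, polarity=polarity, prominence_k=prominence_k, refractory_s=refractory_s
        )
    except TooFewBeatsError as e:
        raise TooFewBeatsError(f"[detect_contractions] {e}", e.n_events) from e
    except FlyheartError as e:
        raise type(e)(f"[detect_contractions] {e}") from e
    try:
        diam = measure_diameters(kymo, events, n_lines=n_diameter_lines)
    except FlyheartError as e:
        raise type(e)(f"[measure_diameters] {e}") from e

    return CardiacMetrics(
        hr=heart_rate(events, hr_strategy),
        ai=arrhythmicity_index(events, ai_strategy),
        fs=fractional_shortening(diam),
        dd=diam.diastolic_diameter,
        sd=diam.systolic_diameter,
        n_beats=events.n_events,
        condition=condition,
    )


def metrics_delta(btp: CardiacMetrics, atp: CardiacMetrics) -> MetricsDelta:
    """ATP - BTP endpoint differences for one paired animal."""
    return MetricsDelta(d_hr=atp.hr - btp.hr, d_ai=atp.ai - btp.ai, d_fs=atp.fs - btp.fs)
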