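"""Batch drivers binding the stages together (used by the CLI and analysis scripts)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .beats import detect_contractions, extract_profile
from .config import RunConfig
from .exceptions import FlyheartError
from .kymo import LineSpec, build_kymograph, suggest_line
from .metrics import compute_metrics
from .poincare import ellipse_delta, fit_ellipse, lag_pairs, plot_poincare

__all__ = ["analyze_manifest", "ellipse_table", "poincare_figures"]

logger = logging.getLogger(__name__)


def _load_recording(path: Path, config: RunConfig):
    """Read a TIFF as a kymograph; multi-page stacks go through line scanning."""
    data, meta = _io.read_stack(path)
    fps = float(meta.get("frame_rate", 100.0))
    px = float(meta.get("pixel_size", 1.0))
    if data.ndim == 3:  # stack: build the kymograph along a suggested line
        line = suggest_line(data)
        return build_kymograph(data, line, pixel_size=px, frame_rate=fps)
    from .kymo import KymographImage

    return KymographImage(intensity=data, pixel_size=px, frame_rate=fps, metadata=meta)


def analyze_manifest(
    manifest: pd.DataFrame, config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-recording metrics and ellipse rows for a cohort manifest.

    Returns ``(metrics, ellipses)`` tables.  Per-recording failures are
    logged as warnings and skipped; the batch never aborts on one bad file.
    """
    config = config or RunConfig()
    if manifest.empty:
        raise ValueError("empty manifest")
    metric_rows, ellipse_rows = [], []
    for _, row in manifest.iterrows():
        rid = f"{row['animal_id']}_{row['condition']}"
        try:
            kymo = _load_recording(Path(row["path"]), config)
            m = compute_metrics(kymo, condition=row["condition"], **config.metrics_kwargs())
            trace = extract_profile(
                kymo, window=config.smoothing_window, row_strategy=config.row_strategy
            )
            events = detect_contractions(
                trace,
                polarity=config.polarity,
                prominence_k=config.prominence_k,
                refractory_s=config.refractory_s,
            )
            ellipse = fit_ellipse(lag_pairs(events), level=config.ellipse_level)
        except (FlyheartError, OSError, ValueError) as e:
            logger.warning("recording %s failed: %s", rid, e)
            continue
        metric_rows.append(
            {
                "recording_id": rid,
                "animal_id": row["animal_id"],
                "strain": row.get("strain"),
                "treatment": row.get("treatment"),
                "condition": row["condition"],
                "hr_bpm": m.hr,
                "ai_au": m.ai,
                "fs_pct": m.fs,
                "dd_um": m.dd,
                "sd_um": m.sd,
                "n_beats": m.n_beats,
                "config_hash": config.hash(),
            }
        )
        scale = 1e6 if config.area_units == "ms2" else 1.0
        ellipse_rows.append(
            {
                "recording_id": rid,
                "animal_id": row["animal_id"],
                "condition": row["condition"],
                "center_n": ellipse.center[0],
                "center_n1": ellipse.center[1],
                "cov_xx": ellipse.covariance[0, 0],
                "cov_xy": ellipse.covariance[0, 1],
                "cov_yy": ellipse.covariance[1, 1],
                "level": ellipse.level,
                "area": ellipse.area * scale,
                "area_units": config.area_units,
                "degenerate": ellipse.degenerate,
            }
        )
    return pd.DataFrame(metric_rows), pd.DataFrame(ellipse_rows)


def ellipse_table(ellipses: pd.DataFrame) -> pd.DataFrame:
    """Paired BTP/ATP ellipse areas with the percent change per animal."""
    wide = ellipses.pivot_table(index="animal_id", columns="condition", values="area",
                                aggfunc="first").dropna()
    out = wide.rename(columns={"BTP": "area_btp", "ATP": "area_atp"}).reset_index()
    out["delta_pct"] = np.where(
        out["area_btp"] > 0, (out["area_atp"] - out["area_btp"]) / out["area_btp"] * 100.0, np.nan
    )
    return out


def poincare_figures(
    series_by_condition: dict[str, object], out_path: str, level: float = 0.99, title: str | None = None
) -> str:
    """Superimposed BTP/ATP Poincare figure for one animal."""
    pb = lag_pairs(series_by_condition["BTP"])
    pa = lag_pairs(series_by_condition["ATP"]) if "ATP" in series_by_condition else None
    eb = fit_ellipse(pb, level)
    ea = fit_ellipse(pa, level) if pa is not None else None
    plot_poincare(pb, eb, pa, ea, path=out_path, title=title)
    return out_path
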