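"""Reading and writing the pipeline's file formats.

Stacks are multi-page TIFF, kymographs single-page TIFF, each with a JSON
sidecar carrying frame rate, pixel size, labels and seed.  Tables (manifest,
events, intervals, metrics, ellipses, comparisons) are plain CSV via pandas;
cohort designs and run configurations are JSON or YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .beats import BeatIntervalSeries
from .kymo import KymographImage

__all__ = [
    "write_kymograph",
    "read_kymograph",
    "write_stack",
    "read_stack",
    "write_events_csv",
    "read_events_csv",
    "load_mapping",
    "dump_mapping",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_kymograph(path: str | Path, kymo: KymographImage) -> Path:
    """Write a kymograph as single-page float32 TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, kymo.intensity.astype(np.float32))
    meta = {
        "frame_rate": kymo.frame_rate,
        "pixel_size": kymo.pixel_size,
        **{k: v for k, v in kymo.metadata.items() if _jsonable(v)},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_kymograph(path: str | Path) -> KymographImage:
    """Read a kymograph TIFF; metadata comes from the JSON sidecar."""
    path = Path(path)
    intensity = tifffile.imread(path).astype(float)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return KymographImage(
        intensity=intensity,
        pixel_size=float(meta.get("pixel_size", 1.0)),
        frame_rate=float(meta.get("frame_rate", 100.0)),
        metadata=meta,
    )


def write_stack(
    path: str | Path, stack: np.ndarray, *, frame_rate: float, pixel_size: float, **extra
) -> Path:
    """Write a (frames, height, width) stack as multi-page float32 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, np.float32))
    meta = {"frame_rate": frame_rate, "pixel_size": pixel_size}
    meta.update({k: v for k, v in extra.items() if _jsonable(v)})
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF stack and its sidecar metadata."""
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return stack, meta


def write_events_csv(path: str | Path, series: BeatIntervalSeries, recording_id: str) -> Path:
    """Events CSV: recording_id, event_index, time_s."""
    path = Path(path)
    pd.DataFrame(
        {
            "recording_id": recording_id,
            "event_index": np.arange(series.n_events),
            "time_s": series.event_times,
        }
    ).to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path, duration: float) -> dict[str, BeatIntervalSeries]:
    """Read an events CSV back into per-recording interval series."""
    df = pd.read_csv(path)
    return {
        rid: BeatIntervalSeries(event_times=g.sort_values("event_index")["time_s"].to_numpy(),
                                duration=duration)
        for rid, g in df.groupby("recording_id")
    }


def load_mapping(path: str | Path) -> dict:
    """Load a JSON or YAML mapping (design or config file)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return data


def dump_mapping(path: str | Path, data: dict) -> Path:
    """Write a mapping as JSON or YAML depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1))
    return path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
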