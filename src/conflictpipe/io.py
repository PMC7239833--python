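"""Readers and writers for the pipeline's plain-text and TIFF formats.

Event logs, fluorescence traces, spot sets and density tables are
delimited text with unit-bearing headers; images are single-channel
TIFF; ground truth and session summaries travel as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fos import DensityRecord, GrayImage, SpotSet
from .photometry import RawFluorescenceTrace
from .task import EventStream, SessionSummary

__all__ = [
    "write_events", "read_events",
    "write_trace", "read_trace",
    "write_image", "read_image",
    "write_spots", "read_spots",
    "write_density_table", "read_density_table",
    "write_summary", "read_summary",
    "write_json", "read_json",
    "load_yaml", "dump_yaml",
]


def write_events(stream: EventStream, path: str | Path) -> None:
    stream.frame.to_csv(path, index=False, float_format="%.6f")


def read_events(path: str | Path) -> EventStream:
    return EventStream(pd.read_csv(path))


def write_trace(trace: RawFluorescenceTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "F": trace.F}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_trace(path: str | Path, sampling_rate: float | None = None) -> RawFluorescenceTrace:
    frame = pd.read_csv(path)
    t = frame["time_s"].to_numpy(dtype=float)
    if sampling_rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer sampling rate from a single sample")
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    return RawFluorescenceTrace(time=t, F=frame["F"].to_numpy(dtype=float),
                                sampling_rate=sampling_rate)


def write_image(image: np.ndarray | GrayImage, path: str | Path) -> None:
    pixels = image.pixels if isinstance(image, GrayImage) else image
    arr = np.asarray(pixels)
    if arr.dtype.kind == "f":
        arr = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_image(path: str | Path, pixel_size: float | None = None,
               polarity: str = "bright_spots") -> GrayImage:
    arr = tifffile.imread(path)
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return GrayImage(pixels=arr.astype(float), bit_depth=bit_depth,
                     pixel_size=pixel_size, polarity=polarity)


def write_spots(spots: SpotSet, path: str | Path) -> None:
    pd.DataFrame(
        {"row": spots.coordinates[:, 0], "col": spots.coordinates[:, 1],
         "peak": spots.peak_values}
    ).to_csv(path, index=False, float_format="%.3f")


def read_spots(path: str | Path) -> SpotSet:
    frame = pd.read_csv(path)
    return SpotSet(frame[["row", "col"]].to_numpy(dtype=float),
                   frame["peak"].to_numpy(dtype=float))


def write_density_table(records: list[DensityRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"roi": r.roi_name, "count": r.count, "area_px2": r.area_px2,
             "density": r.density}
            for r in records
        ]
    ).to_csv(path, index=False)


def read_density_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summary(summary: SessionSummary, path: str | Path) -> None:
    """JSON for a `.json` suffix, one-row delimited text otherwise."""
    path = Path(path)
    d = summary.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, default=float) + "\n")
    else:
        flat = {k: v for k, v in d.items() if k != "latency_median_by_outcome"}
        for outcome, med in d["latency_median_by_outcome"].items():
            flat[f"latency_median_{outcome}_s"] = med
        pd.DataFrame([flat]).to_csv(path, index=False)


def read_summary(path: str | Path) -> SessionSummary:
    d = json.loads(Path(path).read_text())
    return SessionSummary(**{**d, "latency_median_by_outcome":
                             d["latency_median_by_outcome"]})


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
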