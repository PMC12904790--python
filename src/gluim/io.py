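"""File I/O: TIFF movies with JSON sidecars, CSV traces/logs/tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthgen import KineticParams, SyntheticMovie

__all__ = [
    "save_movie",
    "load_movie",
    "write_trace_csv",
    "read_trace_csv",
    "write_events_csv",
    "read_events_csv",
]


def save_movie(out_dir, movie: SyntheticMovie) -> Path:
    """Write a movie as multi-page TIFF plus JSON sidecar; ground-truth
    footprints, traces and event trains go to sibling files when present."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "movie.tif", np.asarray(movie.frames))
    meta = {
        "frame_rate": movie.frame_rate,
        "shape": list(movie.frames.shape),
        "ground_truth": {},
    }
    gt = movie.ground_truth
    if "footprints" in gt:
        tifffile.imwrite(
            out / "footprints.tif",
            np.asarray(gt["footprints"], dtype=np.float32),
            photometric="minisblack",
        )
        meta["ground_truth"]["footprints"] = "footprints.tif"
    if "traces" in gt:
        np.savetxt(out / "traces.csv", np.asarray(gt["traces"]).T, delimiter=",")
        meta["ground_truth"]["traces"] = "traces.csv"
    if "trains" in gt:
        rows = [
            {"site_id": tr.site_id, "time_s": t} for tr in gt["trains"] for t in tr.event_times
        ]
        pd.DataFrame(rows, columns=["site_id", "time_s"]).to_csv(out / "events.csv", index=False)
        meta["ground_truth"]["trains"] = "events.csv"
    if "kinetics" in gt:
        meta["ground_truth"]["kinetics"] = dataclasses.asdict(gt["kinetics"])
    if "config" in gt:
        meta["ground_truth"]["config"] = dataclasses.asdict(gt["config"])
    (out / "movie.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def load_movie(movie_dir) -> SyntheticMovie:
    d = Path(movie_dir)
    meta = json.loads((d / "movie.json").read_text())
    frames = tifffile.imread(d / "movie.tif")
    gt = {}
    gmeta = meta.get("ground_truth", {})
    if "footprints" in gmeta:
        gt["footprints"] = tifffile.imread(d / gmeta["footprints"])
    if "traces" in gmeta:
        gt["traces"] = np.loadtxt(d / gmeta["traces"], delimiter=",", ndmin=2).T
    if "kinetics" in gmeta:
        gt["kinetics"] = KineticParams(**gmeta["kinetics"])
    return SyntheticMovie(frames=frames, frame_rate=meta["frame_rate"], ground_truth=gt)


def write_trace_csv(path, values, rate: float, t_start: float = 0.0) -> None:
    values = np.asarray(values, dtype=float)
    t = t_start + np.arange(values.size) / rate
    pd.DataFrame({"time_s": t, "value": values}).to_csv(path, index=False)


def read_trace_csv(path):
    """Returns (values, rate) inferred from the time column."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    rate = 1.0 / np.median(np.diff(t)) if t.size > 1 else 1.0
    return df["value"].to_numpy(float), float(rate)


def write_events_csv(path, times, labels=None) -> None:
    times = np.asarray(times, dtype=float)
    if labels is None:
        labels = ["event"] * times.size
    pd.DataFrame({"time_s": times, "label": labels}).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
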