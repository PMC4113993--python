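"""Delimited-text and JSON I/O for every pipeline stage.

Formats (all plain text, pandas-backed):

- velocity frames: CSV with columns x_um, y_um, u_um_per_s, v_um_per_s,
  frame, t_s
- waveforms: CSV with columns frame, t_s, node_index, x_um, y_um
- scalar signals / phase series: CSV with columns t_s, value (one file per
  channel) or t_s, value1, value2
- ground truth and summaries: JSON (numpy arrays stored as lists)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rft import WaveformFrame
from .stokeslet import VelocityField

__all__ = [
    "write_velocity_frames", "read_velocity_frames",
    "write_waveforms", "read_waveforms",
    "write_signal", "read_signal",
    "write_json", "read_json",
]


def write_velocity_frames(frames: list[VelocityField], path: str | Path) -> None:
    parts = []
    for i, f in enumerate(frames):
        parts.append(pd.DataFrame({
            "x_um": f.points[:, 0], "y_um": f.points[:, 1],
            "u_um_per_s": f.velocities[:, 0], "v_um_per_s": f.velocities[:, 1],
            "frame": i, "t_s": f.t,
        }))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_velocity_frames(path: str | Path) -> list[VelocityField]:
    df = pd.read_csv(path)
    frames = []
    for _, g in df.groupby("frame", sort=True):
        frames.append(VelocityField(
            points=g[["x_um", "y_um"]].to_numpy(),
            velocities=g[["u_um_per_s", "v_um_per_s"]].to_numpy(),
            t=float(g["t_s"].iloc[0])))
    return frames


def write_waveforms(frames: list[WaveformFrame], path: str | Path) -> None:
    parts = []
    for i, f in enumerate(frames):
        parts.append(pd.DataFrame({
            "frame": i, "t_s": f.t,
            "node_index": np.arange(len(f.nodes)),
            "x_um": f.nodes[:, 0], "y_um": f.nodes[:, 1],
        }))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_waveforms(path: str | Path) -> list[WaveformFrame]:
    df = pd.read_csv(path)
    frames = []
    for _, g in df.groupby("frame", sort=True):
        g = g.sort_values("node_index")
        frames.append(WaveformFrame(nodes=g[["x_um", "y_um"]].to_numpy(),
                                    t=float(g["t_s"].iloc[0])))
    return frames


def write_signal(t: np.ndarray, values: np.ndarray | dict, path: str | Path) -> None:
    if isinstance(values, dict):
        pd.DataFrame({"t_s": t, **values}).to_csv(path, index=False)
    else:
        pd.DataFrame({"t_s": t, "value": values}).to_csv(path, index=False)


def read_signal(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
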