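"""CSV / JSON readers and writers for recordings, fields and results.

Recording CSV dialect: columns ``label,x_mm,y_mm,t_beat1_ms,...``;
an empty cell marks a missing activation (stored as NaN).  Fields are
exported flat (one row per grid node) so they re-load with any table
tool.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import ScalarField, VectorField
from .rbf import MultisiteRecording

__all__ = [
    "read_recording_csv",
    "write_recording_csv",
    "write_scalar_field_csv",
    "write_vector_field_csv",
    "write_manifest",
]


def write_recording_csv(recording: MultisiteRecording, path: str | Path) -> None:
    labels = recording.site_labels or [f"S{i}" for i in range(recording.n_sites)]
    cols = {"label": labels,
            "x_mm": recording.positions[:, 0],
            "y_mm": recording.positions[:, 1]}
    for b in range(recording.n_beats):
        cols[f"t_beat{b + 1}_ms"] = recording.times[:, b]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_recording_csv(path: str | Path, cycle_length: float = 150.0) -> MultisiteRecording:
    df = pd.read_csv(path)
    required = {"label", "x_mm", "y_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: recording CSV needs columns {sorted(required)}")
    beat_cols = [c for c in df.columns if c.startswith("t_beat")]
    if not beat_cols:
        raise ValueError(f"{path}: no t_beat*_ms columns found")
    beat_cols.sort(key=lambda c: int("".join(ch for ch in c if ch.isdigit())))
    bad = df[df[["x_mm", "y_mm"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: missing coordinates in row(s) {list(bad.index)}")
    return MultisiteRecording(
        positions=df[["x_mm", "y_mm"]].to_numpy(float),
        times=df[beat_cols].to_numpy(float),
        cycle_length=cycle_length,
        site_labels=tuple(df["label"].astype(str)),
    )


def _grid_frame(grid) -> pd.DataFrame:
    xx, yy = np.meshgrid(grid.x, grid.y)
    return pd.DataFrame({"x_mm": xx.ravel(), "y_mm": yy.ravel()})


def write_scalar_field_csv(field: ScalarField, path: str | Path,
                           value_name: str = "divergence_per_mm") -> None:
    df = _grid_frame(field.grid)
    df[value_name] = field.values.ravel()
    df["valid"] = field.valid.ravel()
    df.to_csv(path, index=False)


def write_vector_field_csv(field: VectorField, path: str | Path) -> None:
    df = _grid_frame(field.grid)
    df["vx_cm_s"] = field.vx.ravel()
    df["vy_cm_s"] = field.vy.ravel()
    df["speed_cm_s"] = field.speed.ravel()
    df["valid"] = field.valid.ravel()
    df.to_csv(path, index=False)


def write_manifest(path: str | Path, command: str, config: dict) -> None:
    """Reproducibility manifest: command, parameters, package version."""
    from . import __version__

    payload = {"command": command, "config": config, "divmap_version": __version__}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
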