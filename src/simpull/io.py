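"""Text-based interchange formats for traces, step tables and distributions.

Traces travel as TSV with columns (spot_id, frame, intensity), one row
per frame, frames contiguous from 0 and of equal length within a file;
ground-truth labels go in a sidecar table.  Integer intensities
round-trip bit-identically.  An HDF5 container is offered for large
trace sets.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import Trace

__all__ = [
    "read_traces",
    "write_traces",
    "read_truth",
    "write_steps",
    "read_steps",
    "write_traces_hdf5",
    "read_traces_hdf5",
    "TraceFormatError",
]

TRACE_COLUMNS = ("spot_id", "frame", "intensity")


class TraceFormatError(ValueError):
    """A trace table violates the interchange format."""


def write_traces(traces: list[Trace], path: str | Path, truth_path: str | Path | None = None) -> Path:
    """Write traces as TSV; optionally a truth sidecar (spot_id, truth)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "spot_id": tr.spot_id,
                    "frame": np.arange(len(tr)),
                    "intensity": tr.intensities,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    if truth_path is not None:
        pd.DataFrame(
            {
                "spot_id": [t.spot_id for t in traces],
                "truth": [t.truth if t.truth is not None else pd.NA for t in traces],
            }
        ).to_csv(truth_path, sep="\t", index=False)
    return path


def read_traces(path: str | Path, frame_interval: float = 0.1) -> list[Trace]:
    """Read a trace TSV back into Trace objects (grouped by spot_id).

    Raises :class:`TraceFormatError` naming the offending spot for
    missing columns, non-contiguous frames, or mixed trace lengths.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {missing}")
    if df.empty:
        warnings.warn(f"{path}: no traces found", stacklevel=2)
        return []
    traces: list[Trace] = []
    length: int | None = None
    for spot_id, g in df.groupby("spot_id", sort=True):
        frames = g["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            raise TraceFormatError(
                f"{path}: frames for spot {spot_id!r} are not contiguous from 0"
            )
        if length is None:
            length = len(frames)
        elif len(frames) != length:
            raise TraceFormatError(
                f"{path}: spot {spot_id!r} has {len(frames)} frames, expected {length}"
            )
        traces.append(
            Trace(
                spot_id=str(spot_id),
                intensities=g["intensity"].to_numpy(dtype=float),
                frame_interval=frame_interval,
            )
        )
    return traces


def read_truth(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.spot_id): int(r.truth) for r in df.itertuples() if pd.notna(r.truth)}


def write_steps(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_steps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "step_count" not in df.columns:
        raise TraceFormatError(f"{path}: missing 'step_count' column")
    if "valid" in df.columns:
        df["valid"] = df["valid"].astype(bool)
    return df


def write_traces_hdf5(traces: list[Trace], path: str | Path) -> Path:
    """Binary container for large trace sets (equal-length traces)."""
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("intensities", data=np.stack([t.intensities for t in traces]))
        f.create_dataset(
            "spot_id", data=np.array([t.spot_id for t in traces], dtype="S")
        )
        truth = np.array([-1 if t.truth is None else t.truth for t in traces])
        f.create_dataset("truth", data=truth)
    return path


def read_traces_hdf5(path: str | Path, frame_interval: float = 0.1) -> list[Trace]:
    import h5py

    with h5py.File(path, "r") as f:
        inten = f["intensities"][:]
        ids = [s.decode() for s in f["spot_id"][:]]
        truth = f["truth"][:]
    return [
        Trace(
            spot_id=ids[i],
            intensities=inten[i],
            frame_interval=frame_interval,
            truth=None if truth[i] < 0 else int(truth[i]),
        )
        for i in range(len(ids))
    ]
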