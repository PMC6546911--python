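"""File formats: trace CSV, ground-truth sidecars, flat config, manifests.

Conventions enforced at every reader/writer: frames are 0-based, times are in
seconds, FRET is dimensionless, CSVs are UTF-8 with headers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .photophysics import Trace

__all__ = [
    "write_traces",
    "read_traces",
    "write_sidecar",
    "read_sidecar",
    "write_movie",
    "read_movie",
    "load_config_file",
    "save_config_file",
    "write_manifest",
]

TRACE_COLUMNS = ["trace_id", "frame", "time_s", "donor", "acceptor"]


def write_traces(traces: Sequence[Trace], path) -> None:
    """Write traces as one long-format CSV (trace_id, frame, time_s, donor,
    acceptor)."""
    frames = [tr.to_frame() for tr in traces]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACE_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_traces(path) -> list[Trace]:
    """Read traces written by :func:`write_traces`; frames are re-sorted.

    Raises ``ValueError`` naming any missing column.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed trace file {path}: missing column(s) {missing}")
    traces = []
    for tid, g in df.groupby("trace_id", sort=True):
        g = g.sort_values("frame")
        traces.append(
            Trace(
                trace_id=str(tid),
                time=g["time_s"].to_numpy(float),
                donor=g["donor"].to_numpy(float),
                acceptor=g["acceptor"].to_numpy(float),
            )
        )
    return traces


def write_sidecar(traces: Sequence[Trace], path) -> None:
    """Ground-truth metadata sidecar, one row per simulated trace."""
    rows = []
    for tr in traces:
        m = tr.meta
        rows.append(
            {
                "trace_id": tr.trace_id,
                "scheme": m.get("scheme", ""),
                "n_donors": m.get("n_donors", np.nan),
                "true_assoc_frame": m.get("true_assoc_frame"),
                "true_dissoc_frame": m.get("true_dissoc_frame"),
                "seed": m.get("seed"),
            }
        )
    pd.DataFrame(
        rows,
        columns=["trace_id", "scheme", "n_donors", "true_assoc_frame",
                 "true_dissoc_frame", "seed"],
    ).to_csv(path, index=False)


def read_sidecar(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_movie(stack: np.ndarray, path) -> None:
    """Write one channel as a 16-bit multi-page TIFF.

    Photon counts are rounded and clipped to the uint16 range (read noise
    can produce small negative values).
    """
    import tifffile

    data = np.clip(np.rint(np.asarray(stack)), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))


def read_movie(path) -> np.ndarray:
    """Read a movie written by :func:`write_movie` as float (frames, h, w)."""
    import tifffile

    stack = tifffile.imread(path).astype(float)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def load_config_file(path) -> dict:
    """Load a flat key/value YAML config file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a flat key/value mapping")
    return data


def save_config_file(data: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True, default_flow_style=False)


def write_manifest(manifest: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(manifest, indent=2, default=_default))
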