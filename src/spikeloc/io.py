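"""Readers and writers for the on-disk formats.

* Probe geometry: CSV ``channel_id,x,y,z`` (µm) or an equivalent JSON
  dialect — the two round-trip to full float precision and load to equal
  geometries.
* Recording: flat binary (channel-major, little-endian) plus a JSON
  sidecar carrying sampling rate, shape, dtype, geometry path and dead
  mask.
* Ground truth: one JSON document with a list of unit objects.
* Estimates / channel status / metrics: CSV.

Data files are byte-stable for fixed input; run metadata (timestamps,
versions) never goes inside them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ChannelStatus
from .simulate import GroundTruthUnit, ProbeGeometry, Recording

__all__ = [
    "FormatError",
    "read_geometry",
    "write_geometry",
    "read_recording",
    "write_recording",
    "read_ground_truth",
    "write_ground_truth",
    "write_channel_status",
    "write_estimates",
]


class FormatError(ValueError):
    """A file does not match its documented format."""


# ---------------------------------------------------------------------------
# Probe geometry
# ---------------------------------------------------------------------------

_GEOM_COLUMNS = ("channel_id", "x", "y", "z")


def write_geometry(geometry: ProbeGeometry, path: str | Path) -> None:
    """Write CSV (``.csv``) or JSON (anything else)."""
    path = Path(path)
    if path.suffix == ".csv":
        lines = [",".join(_GEOM_COLUMNS)]
        for cid, (x, y, z) in zip(geometry.channel_ids, geometry.positions):
            lines.append(f"{int(cid)},{float(x)!r},{float(y)!r},{float(z)!r}")
        path.write_text("\n".join(lines) + "\n")
    else:
        doc = {
            "name": geometry.name,
            "channel_ids": [int(c) for c in geometry.channel_ids],
            "positions": [[float(v) for v in p] for p in geometry.positions],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")


def read_geometry(path: str | Path) -> ProbeGeometry:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in _GEOM_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"geometry CSV {path} missing column(s) {missing}")
        ids = df["channel_id"].to_numpy()
        dup = df["channel_id"][df["channel_id"].duplicated()]
        if not dup.empty:
            row = int(dup.index[0]) + 2  # header + 1-based
            raise FormatError(
                f"duplicate channel_id {dup.iloc[0]} in {path} at row {row}"
            )
        pos = df[["x", "y", "z"]].to_numpy(dtype=float)
        return ProbeGeometry(channel_ids=ids, positions=pos, name=path.stem)
    doc = json.loads(path.read_text())
    ids = np.asarray(doc["channel_ids"], dtype=int)
    if np.unique(ids).size != ids.size:
        dup = ids[pd.Index(ids).duplicated()][0]
        raise FormatError(f"duplicate channel_id {dup} in {path}")
    return ProbeGeometry(
        channel_ids=ids,
        positions=np.asarray(doc["positions"], dtype=float),
        name=doc.get("name", path.stem),
    )


# ---------------------------------------------------------------------------
# Recording: flat binary + JSON sidecar
# ---------------------------------------------------------------------------


def write_recording(
    recording: Recording, binary_path: str | Path, geometry_path: str | Path | None = None
) -> None:
    """Write channel-major flat binary and a ``<binary>.json`` sidecar.

    If ``geometry_path`` is given the geometry is written there and the
    sidecar references it by (relative) name.
    """
    binary_path = Path(binary_path)
    arr = np.ascontiguousarray(recording.traces, dtype="<f4")
    arr.tofile(binary_path)
    if geometry_path is not None:
        write_geometry(recording.geometry, geometry_path)
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "dtype": "float32",
        "order": "channel_major",
        "geometry_file": Path(geometry_path).name if geometry_path else None,
        "dead_mask": [bool(b) for b in recording.dead_mask],
    }
    Path(str(binary_path) + ".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_recording(
    binary_path: str | Path, geometry: ProbeGeometry | None = None
) -> Recording:
    binary_path = Path(binary_path)
    sidecar_path = Path(str(binary_path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    dtype = {"float32": "<f4", "int16": "<i2"}.get(meta["dtype"])
    if dtype is None:
        raise FormatError(f"unsupported dtype {meta['dtype']!r} in {sidecar_path}")
    traces = np.fromfile(binary_path, dtype=dtype).astype(np.float32)
    n_ch = int(meta["n_channels"])
    if traces.size % n_ch:
        raise FormatError(f"{binary_path}: size not divisible by n_channels={n_ch}")
    traces = traces.reshape(n_ch, -1)
    if geometry is None:
        gfile = meta.get("geometry_file")
        if gfile is None:
            raise FormatError("no geometry supplied and sidecar has no geometry_file")
        geometry = read_geometry(binary_path.parent / gfile)
    return Recording(
        traces=traces,
        sampling_rate=float(meta["sampling_rate"]),
        geometry=geometry,
        dead_mask=np.asarray(meta.get("dead_mask", [False] * n_ch), dtype=bool),
    )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


def write_ground_truth(units: list[GroundTruthUnit], path: str | Path) -> None:
    doc = [
        {
            "unit_id": u.unit_id,
            "position": [float(v) for v in u.position],
            "base_amplitude": u.base_amplitude,
            "spike_times": [float(t) for t in u.spike_times],
            "trough_width_ms": u.trough_width_ms,
            "peak_ratio": u.peak_ratio,
            "duration_ms": u.duration_ms,
        }
        for u in units
    ]
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_ground_truth(path: str | Path) -> list[GroundTruthUnit]:
    doc = json.loads(Path(path).read_text())
    return [
        GroundTruthUnit(
            unit_id=int(u["unit_id"]),
            position=tuple(float(v) for v in u["position"]),
            base_amplitude=float(u.get("base_amplitude", 100.0)),
            spike_times=np.asarray(u["spike_times"], dtype=float),
            trough_width_ms=float(u.get("trough_width_ms", 0.3)),
            peak_ratio=float(u.get("peak_ratio", 0.35)),
            duration_ms=float(u.get("duration_ms", 2.0)),
        )
        for u in doc
    ]


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------


def write_channel_status(status: ChannelStatus, path: str | Path) -> None:
    pd.DataFrame({"channel_id": status.channel_ids, "label": status.labels}).to_csv(
        path, index=False
    )


def write_estimates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
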