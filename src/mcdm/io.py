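"""Delimited-text I/O for signals and records.

Signals are stored as plain text, one column per channel, with ``#``
comment header lines carrying ``key=value`` metadata (sampling rate,
subject id, class label).  Fiducial annotations travel in a JSON sidecar
next to the signal file (``<stem>.fiducials.json``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .synthetic import FiducialSet, MCGRecord, TimeSeries

__all__ = [
    "write_record",
    "read_record",
    "write_series",
    "read_series",
    "fiducial_sidecar_path",
]


def fiducial_sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".fiducials.json")


def _write_delimited(
    path: Path, data: np.ndarray, meta: dict[str, str], delimiter: str
) -> None:
    header = "\n".join(f"{k}={v}" for k, v in meta.items())
    np.savetxt(path, data, delimiter=delimiter, header=header, fmt="%.10g")


def _read_delimited(path: Path, delimiter: str) -> tuple[np.ndarray, dict[str, str]]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line.lstrip("#").strip()
            if "=" in text:
                key, _, value = text.partition("=")
                meta[key.strip()] = value.strip()
    data = np.loadtxt(path, delimiter=delimiter)
    return data, meta


def write_record(record: MCGRecord, path: str | Path, delimiter: str = ",") -> Path:
    """Write an :class:`MCGRecord` as delimited text plus fiducial sidecar."""
    path = Path(path)
    meta = {
        "sampling_rate": repr(record.sampling_rate),
        "subject_id": record.subject_id,
        "class_label": record.class_label or "",
        "n_channels": str(record.n_channels),
    }
    _write_delimited(path, record.channels.T, meta, delimiter)
    if record.fiducials is not None:
        with open(fiducial_sidecar_path(path), "w") as fh:
            json.dump(record.fiducials.to_dict(), fh)
    return path


def read_record(path: str | Path, delimiter: str = ",") -> MCGRecord:
    path = Path(path)
    data, meta = _read_delimited(path, delimiter)
    if data.ndim == 1:
        data = data[:, None]
    fiducials = None
    sidecar = fiducial_sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            fiducials = FiducialSet.from_dict(json.load(fh))
    return MCGRecord(
        channels=data.T,
        sampling_rate=float(meta["sampling_rate"]),
        subject_id=meta.get("subject_id", ""),
        class_label=meta.get("class_label") or None,
        fiducials=fiducials,
    )


def write_series(series: TimeSeries, path: str | Path, delimiter: str = ",") -> Path:
    path = Path(path)
    meta = {"sampling_rate": repr(series.sampling_rate), "name": series.name}
    _write_delimited(path, series.values[:, None], meta, delimiter)
    return path


def read_series(path: str | Path, delimiter: str = ",") -> TimeSeries:
    data, meta = _read_delimited(Path(path), delimiter)
    return TimeSeries(
        values=np.atleast_1d(data).ravel(),
        sampling_rate=float(meta["sampling_rate"]),
        name=meta.get("name", ""),
    )
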