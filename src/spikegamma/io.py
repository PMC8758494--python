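"""Trace I/O.

The pipeline's archival format is CSV (header ``time_s,value``, UTF-8,
'.' decimal) with an optional JSON sidecar carrying metadata the CSV
cannot: sampling rate, units, label. Sampling rate is recovered from the
time column when no sidecar or explicit rate is given; writing stores
full float precision so write -> read round-trips bit-identically.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .core import ParameterError, SpikeTrain, TimeSeries


class TraceIOError(IOError):
    """Raised for missing files, absent metadata, or malformed trace files."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(ts: TimeSeries, path: str | Path) -> Path:
    """Write a trace as CSV with a JSON metadata sidecar.

    Lossless: values are written with ``repr``-level float precision.
    """
    path = Path(path)
    times = ts.times
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time_s", "value"])
            for t, v in zip(times, ts.samples):
                writer.writerow([repr(float(t)), repr(float(v))])
    except OSError as exc:  # unwritable path
        raise TraceIOError(f"cannot write trace to {path}: {exc}") from exc
    meta = {
        "sampling_rate_hz": ts.sampling_rate,
        "t0_s": ts.t0,
        "units": ts.units,
        "label": ts.label,
        "n_samples": len(ts),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return path


def read_trace(
    path: str | Path,
    *,
    sampling_rate: float | None = None,
    units: str | None = None,
    label: str | None = None,
) -> TimeSeries:
    """Read a CSV trace (columns ``time_s,value``).

    Metadata resolution order: explicit arguments, then the JSON sidecar,
    then (for the sampling rate only) the median spacing of the time
    column. A file with a single sample and no stated rate is an error.
    """
    path = Path(path)
    if not path.exists():
        raise TraceIOError(f"no such trace file: {path}")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))

    times: list[float] = []
    values: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["time_s", "value"]:
            raise TraceIOError(f"{path}: expected header 'time_s,value', got {header}")
        for row in reader:
            if not row:
                continue
            times.append(float(row[0]))
            values.append(float(row[1]))
    if not values:
        raise TraceIOError(f"{path}: trace contains no samples")

    rate = sampling_rate if sampling_rate is not None else meta.get("sampling_rate_hz")
    if rate is None:
        if len(times) < 2:
            raise TraceIOError(
                f"{path}: sampling rate absent from sidecar/config and not inferable"
            )
        rate = 1.0 / float(np.median(np.diff(times)))
    t0 = float(times[0]) if times else float(meta.get("t0_s", 0.0))
    try:
        return TimeSeries(
            samples=np.asarray(values, dtype=float),
            sampling_rate=float(rate),
            t0=t0,
            units=units if units is not None else meta.get("units", "arbitrary"),
            label=label if label is not None else meta.get("label", path.stem),
        )
    except ParameterError as exc:
        raise TraceIOError(f"{path}: {exc}") from exc


def write_spike_train(st: SpikeTrain, path: str | Path) -> Path:
    path = Path(path)
    payload = {"duration_s": st.duration, "times_s": [float(t) for t in st.times]}
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return path


def read_spike_train(path: str | Path) -> SpikeTrain:
    path = Path(path)
    if not path.exists():
        raise TraceIOError(f"no such spike-train file: {path}")
    payload = json.loads(path.read_text(encoding="utf-8"))
    return SpikeTrain(
        times=np.asarray(payload["times_s"], dtype=float),
        duration=float(payload["duration_s"]),
    )
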