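"""Time-series I/O and the core :class:`Trace` container.

All analysis code in this package works on uniformly sampled,
single-channel traces with fixed internal units: picoamperes for
voltage-clamp current, millivolts for current-clamp voltage, seconds,
hertz, and megaohms.  Unit conversion, if any, happens at the I/O
boundary, never inside the analysis functions.

Two plain-text layouts are supported for a single trace:

* a header form — comment lines ``# key=value`` (at minimum
  ``sampling_rate_hz``) followed by a single ``value`` column;
* a two-column form — ``time_s,value`` with a strictly uniform time
  grid (checked to 1 ppm).

Multi-sweep recordings (e.g. a current-step family) are stored in an
HDF5 container: one group per cell, one dataset per sweep, metadata in
attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

CHANNEL_ROLES = (
    "vclamp_current",
    "cclamp_voltage",
    "neurogram_cnx",
    "neurogram_snii",
)

#: header keys that map to Trace fields rather than free metadata
_RESERVED_KEYS = {"sampling_rate_hz", "channel_role", "t0_s"}

_FLOAT_FMT = "%.17g"


class TraceFormatError(ValueError):
    """Raised when a time-series file violates the documented layout."""


class TableSchemaError(ValueError):
    """Raised when records passed to :func:`write_table` are not homogeneous."""


@dataclass
class Trace:
    """A uniformly sampled single-channel recording.

    Parameters
    ----------
    samples:
        Sample values.  Units depend on ``channel_role``: pA for
        ``vclamp_current``, mV for ``cclamp_voltage``, arbitrary
        integrated units for the neurogram roles.
    sampling_rate:
        Samples per second (Hz); must be positive.
    channel_role:
        One of :data:`CHANNEL_ROLES`.
    t0:
        Time of the first sample, seconds.
    metadata:
        Free key-value pairs (neuron id, group label, drug epoch, ...).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_role: str = "vclamp_current"
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(
                f"unknown channel_role {self.channel_role!r}; expected one of {CHANNEL_ROLES}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (``n_samples / sampling_rate``)."""
        return self.n_samples / self.sampling_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


def _parse_header(path: Path) -> dict:
    header: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" not in body:
                continue
            key, _, value = body.partition("=")
            header[key.strip()] = value.strip()
    return header


def _coerce(value: str):
    try:
        f = float(value)
    except ValueError:
        return value
    return int(f) if f.is_integer() and "." not in value and "e" not in value.lower() else f


def read_timeseries(path, format: str = "csv") -> Trace:
    """Read a single trace from CSV/TSV (or an HDF5 container member).

    For the container format address a dataset as
    ``"file.h5::group/dataset"``; a bare container path is accepted when
    it holds exactly one dataset.

    Raises
    ------
    TraceFormatError
        If the sampling rate is missing/ambiguous or a time column is
        non-uniform beyond 1 ppm.
    """
    if format == "container":
        return _read_container_member(str(path))
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    sep = "," if format == "csv" else "\t"
    header = _parse_header(path)
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    if "value" not in df.columns:
        raise TraceFormatError(f"{path}: no 'value' column")
    values = df["value"].to_numpy(dtype=float)

    rate_from_header = header.get("sampling_rate_hz")
    rate = None
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise TraceFormatError(f"{path}: time column too short to infer a rate")
        steps = np.diff(t)
        step = float(np.median(steps))
        if step <= 0 or np.max(np.abs(steps - step)) > 1e-6 * step:
            raise TraceFormatError(f"{path}: time grid non-uniform beyond 1 ppm")
        rate = 1.0 / step
        if rate_from_header is not None and abs(rate - float(rate_from_header)) > 1e-6 * rate:
            raise TraceFormatError(
                f"{path}: header sampling rate {rate_from_header} disagrees with time column"
            )
        t0 = float(t[0])
    else:
        if rate_from_header is None:
            raise TraceFormatError(f"{path}: sampling rate neither declared nor inferable")
        rate = float(rate_from_header)
        t0 = float(header.get("t0_s", 0.0))

    metadata = {
        k: _coerce(v) for k, v in header.items() if k not in _RESERVED_KEYS
    }
    role = header.get("channel_role", "vclamp_current")
    return Trace(values, rate, channel_role=role, t0=t0, metadata=metadata)


def write_timeseries(trace: Trace, path, format: str = "csv", layout: str = "header") -> None:
    """Write a trace losslessly (full float precision).

    ``layout="header"`` (default) stores the rate in a comment header
    with a single value column; ``layout="time"`` writes an explicit
    ``time_s`` column.
    """
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    sep = "," if format == "csv" else "\t"
    lines = [
        f"# sampling_rate_hz={trace.sampling_rate!r}",
        f"# channel_role={trace.channel_role}",
        f"# t0_s={trace.t0!r}",
    ]
    for k, v in trace.metadata.items():
        if k in _RESERVED_KEYS:
            continue
        lines.append(f"# {k}={v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        if layout == "header":
            fh.write("value\n")
            np.savetxt(fh, trace.samples, fmt=_FLOAT_FMT)
        elif layout == "time":
            fh.write(f"time_s{sep}value\n")
            cols = np.column_stack([trace.times(), trace.samples])
            np.savetxt(fh, cols, fmt=_FLOAT_FMT, delimiter=sep)
        else:
            raise ValueError(f"unknown layout {layout!r}")


def write_container(path, traces: Mapping[str, Trace]) -> None:
    """Write traces to an HDF5 container, keys as ``group/dataset`` paths."""
    with h5py.File(path, "w") as h5:
        for key, trace in traces.items():
            ds = h5.create_dataset(key, data=trace.samples)
            ds.attrs["sampling_rate_hz"] = trace.sampling_rate
            ds.attrs["channel_role"] = trace.channel_role
            ds.attrs["t0_s"] = trace.t0
            for k, v in trace.metadata.items():
                ds.attrs[f"meta_{k}"] = v


def read_container(path) -> dict:
    """Read every dataset of an HDF5 container into ``{key: Trace}``."""
    out: dict = {}

    def visit(name, obj):
        if isinstance(obj, h5py.Dataset):
            out[name] = _trace_from_dataset(obj)

    with h5py.File(path, "r") as h5:
        h5.visititems(visit)
    return out


def _trace_from_dataset(ds: h5py.Dataset) -> Trace:
    meta = {}
    for k, v in ds.attrs.items():
        if k.startswith("meta_"):
            meta[k[5:]] = v.item() if hasattr(v, "item") else v
    return Trace(
        ds[()],
        float(ds.attrs["sampling_rate_hz"]),
        channel_role=str(ds.attrs.get("channel_role", "vclamp_current")),
        t0=float(ds.attrs.get("t0_s", 0.0)),
        metadata=meta,
    )


def _read_container_member(address: str) -> Trace:
    if "::" in address:
        fname, _, key = address.partition("::")
        with h5py.File(fname, "r") as h5:
            if key not in h5:
                raise TraceFormatError(f"{fname}: no dataset {key!r}")
            return _trace_from_dataset(h5[key])
    traces = read_container(address)
    if len(traces) != 1:
        raise TraceFormatError(
            f"{address}: container holds {len(traces)} datasets; address one as 'file::group/dataset'"
        )
    return next(iter(traces.values()))


def write_table(rows, path, format: str = "csv") -> None:
    """Write homogeneous records as a delimited table with a header row.

    ``rows`` may be dictionaries or dataclass instances; every record
    must expose the same keys, otherwise :class:`TableSchemaError` is
    raised.  Numeric fields are written at full float precision.
    """
    from dataclasses import asdict, is_dataclass

    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    records = [asdict(r) if is_dataclass(r) else dict(r) for r in rows]
    if records:
        keys = list(records[0].keys())
        for i, rec in enumerate(records):
            if list(rec.keys()) != keys:
                raise TableSchemaError(f"record {i} keys differ from record 0")
        df = pd.DataFrame.from_records(records, columns=keys)
    else:
        df = pd.DataFrame()
    sep = "," if format == "csv" else "\t"
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


def read_table(path, format: str = "csv") -> pd.DataFrame:
    sep = "," if format == "csv" else "\t"
    return pd.read_csv(path, sep=sep)
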