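"""Reading, validating and writing 1-D physiological signal traces.

A trace is stored as RFC-4180-style CSV, either two columns ``time,value``
(sampling rate inferred from the time axis) or a single ``value`` column with
the rate supplied by the caller or by a JSON sidecar ``<path>.meta.json``
holding ``fs``, ``units`` and ``label``.  Every downstream stage consumes only
validated :class:`SignalTrace` objects, so malformed files can never reach the
model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, PairingError, TraceIOError, ValidationError

__all__ = ["SignalTrace", "PairedRecord", "read_trace", "write_trace", "load_paired"]

# relative tolerance on time-step uniformity when fs is inferred from a time column
_UNIFORMITY_RTOL = 0.01


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled one-dimensional waveform.

    Parameters
    ----------
    samples : ndarray
        Real amplitudes (mmHg, mV or arbitrary units).
    fs : float
        Sampling rate in Hz, strictly positive.
    label : str
        Free-text channel name.
    units : str
        Free-text unit string.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValidationError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size < 2:
            raise ValidationError(f"trace needs >= 2 samples, got {samples.size}")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("trace contains NaN or infinite samples")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValidationError(f"sampling rate must be positive and finite, got {self.fs}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    def with_samples(self, samples: np.ndarray) -> "SignalTrace":
        """Same metadata, new sample values (used by filters)."""
        return SignalTrace(samples=samples, fs=self.fs, label=self.label, units=self.units)


@dataclass(frozen=True)
class PairedRecord:
    """A source/target trace pair sharing length and sampling rate.

    Resampling is out of scope: mismatched inputs are rejected outright.
    """

    source: SignalTrace
    target: SignalTrace
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.source) != len(self.target):
            raise PairingError(
                f"length mismatch: source {len(self.source)} vs target {len(self.target)}"
            )
        if not np.isclose(self.source.fs, self.target.fs, rtol=1e-9, atol=0.0):
            raise PairingError(
                f"sampling-rate mismatch: source {self.source.fs} Hz vs target {self.target.fs} Hz"
            )

    def __len__(self) -> int:
        return len(self.source)

    @property
    def fs(self) -> float:
        return self.source.fs


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        return {}
    try:
        return json.loads(sc.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"unreadable metadata sidecar {sc}: {exc}") from exc


def read_trace(
    path: str | Path,
    fs: float | None = None,
    column: str | int | None = None,
) -> SignalTrace:
    """Read a trace from CSV.

    ``(time, value)`` files infer ``fs`` from the median time step and require
    the steps to be uniform within 1% relative tolerance; value-only files
    need ``fs`` from the argument or the JSON sidecar.  ``column`` selects the
    value column by name or position when the file has several.
    """
    path = Path(path)
    if not path.exists():
        raise TraceIOError(f"no such file: {path}")
    meta = _read_sidecar(path)

    try:
        # header sniffing: a first row that parses as floats means "no header"
        probe = pd.read_csv(path, header=None, nrows=1)
        has_header = not all(
            isinstance(v, (int, float, np.integer, np.floating)) for v in probe.iloc[0]
        )
        # round_trip: the default parser is not correctly rounded, which
        # would break the lossless read/write contract
        df = pd.read_csv(
            path, header=0 if has_header else None, float_precision="round_trip"
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
    if not has_header:
        df.columns = ["time", "value"] if df.shape[1] == 2 else list(range(df.shape[1]))

    cols = [str(c).strip().lower() for c in df.columns]
    time_idx = cols.index("time") if "time" in cols else None

    if column is not None:
        if isinstance(column, int):
            if not 0 <= column < df.shape[1]:
                raise FormatError(f"{path}: no column index {column} (file has {df.shape[1]})")
            value_col = df.iloc[:, column]
        else:
            if str(column).strip().lower() not in cols:
                raise FormatError(f"{path}: no column named {column!r}")
            value_col = df.iloc[:, cols.index(str(column).strip().lower())]
    elif time_idx is not None and df.shape[1] >= 2:
        value_col = df.iloc[:, 1 if time_idx == 0 else 0]
    elif df.shape[1] == 1:
        value_col = df.iloc[:, 0]
    elif df.shape[1] == 2 and time_idx is None:
        # bare two-column file: convention is (time, value)
        time_idx = 0
        value_col = df.iloc[:, 1]
    else:
        raise FormatError(
            f"{path}: ambiguous layout with {df.shape[1]} columns; pass column= explicitly"
        )

    values = pd.to_numeric(value_col, errors="coerce").to_numpy(dtype=np.float64)

    if time_idx is not None:
        t = pd.to_numeric(df.iloc[:, time_idx], errors="coerce").to_numpy(dtype=np.float64)
        if np.any(np.isnan(t)):
            raise FormatError(f"{path}: non-numeric entries in time column")
        dt = np.diff(t)
        if dt.size == 0:
            raise ValidationError(f"{path}: trace needs >= 2 samples")
        med = float(np.median(dt))
        if med <= 0:
            raise FormatError(f"{path}: time column is not strictly increasing")
        if np.max(np.abs(dt - med)) > _UNIFORMITY_RTOL * med:
            raise FormatError(
                f"{path}: non-uniform sampling (worst step deviates "
                f">{_UNIFORMITY_RTOL:.0%} from median {med:.6g} s)"
            )
        inferred = 1.0 / med
        if fs is not None and not np.isclose(fs, inferred, rtol=_UNIFORMITY_RTOL):
            raise FormatError(
                f"{path}: explicit fs={fs} Hz contradicts time column ({inferred:.6g} Hz)"
            )
        fs = inferred if fs is None else fs
        # the sidecar stores the exact rate; prefer it over the float-rounded inference
        if "fs" in meta and np.isclose(float(meta["fs"]), fs, rtol=_UNIFORMITY_RTOL):
            fs = float(meta["fs"])
    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        raise ValueError(f"{path}: value-only file needs an explicit fs (argument or sidecar)")

    return SignalTrace(
        samples=values,
        fs=float(fs),
        label=str(meta.get("label", path.stem)),
        units=str(meta.get("units", "")),
    )


def write_trace(trace: SignalTrace, path: str | Path) -> None:
    """Write a trace as ``time,value`` CSV plus a JSON metadata sidecar.

    Round trip: ``read_trace(write_trace(t))`` reproduces the samples at full
    stored precision (17 significant digits) and ``fs`` exactly (the sidecar
    stores it verbatim and takes precedence over the inferred rate).
    """
    path = Path(path)
    header = "time,value"
    body = "\n".join(
        f"{n / trace.fs:.17g},{v:.17g}" for n, v in enumerate(trace.samples)
    )
    try:
        path.write_text(header + "\n" + body + "\n")
        _sidecar_path(path).write_text(
            json.dumps({"fs": trace.fs, "units": trace.units, "label": trace.label}, indent=2)
        )
    except OSError as exc:
        raise TraceIOError(f"cannot write trace to {path}: {exc}") from exc


def load_paired(path_source: str | Path, path_target: str | Path) -> PairedRecord:
    """Read two traces and verify they form a valid pair."""
    source = read_trace(path_source)
    target = read_trace(path_target)
    return PairedRecord(source=source, target=target)
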