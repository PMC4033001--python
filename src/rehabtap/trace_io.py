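"""Force-trace I/O and preprocessing.

A tapping recording is a uniformly sampled force time series (nominally
3 kHz) from a force-sensitive resistor under the tapping finger.  The
preprocessing chain applied before landmark detection is, in order:

1. :func:`trim_edges` — discard the first and last 0.5 s of the recording
   (start-up and hand-withdrawal artifacts);
2. :func:`calibrate` — map raw sensor readings to Newtons through a
   piecewise-linear calibration table;
3. :func:`smooth_bartlett` — convolve with a unit-sum triangular
   (Bartlett) window, 160 samples by default (~53 ms at 3 kHz).

Traces are stored as plain TSV with ``#``-prefixed header lines so files
are diffable and versionable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal.windows import triang

__all__ = [
    "ForceTrace",
    "CalibrationTable",
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "calibrate",
    "trim_edges",
    "smooth_bartlett",
    "preprocess",
]

_UNITS = ("raw", "newton")


class TraceFormatError(ValueError):
    """Raised when a trace file is malformed or a contract is violated."""


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled force time series.

    Parameters
    ----------
    samples
        Force values, one per sample.
    sample_rate_hz
        Sampling rate in Hz (nominally 3000).
    units
        ``"raw"`` (uncalibrated sensor readings) or ``"newton"``.
    recording_id
        Free-form label identifying the recording.
    t0_ms
        Time of the first retained sample in original-recording
        coordinates; nonzero after edge trimming so landmark times stay
        comparable across processing stages.
    """

    samples: np.ndarray
    sample_rate_hz: float
    units: str = "raw"
    recording_id: str = ""
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if arr.ndim != 1 or arr.size < 1:
            raise TraceFormatError("trace must hold at least one sample")
        if not self.sample_rate_hz > 0:
            raise TraceFormatError("sample_rate_hz must be positive")
        if self.units not in _UNITS:
            raise TraceFormatError(f"units must be one of {_UNITS}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def times_ms(self) -> np.ndarray:
        """Sample times in ms, in original-recording coordinates."""
        return self.t0_ms + np.arange(self.samples.size) * (1000.0 / self.sample_rate_hz)


@dataclass(frozen=True)
class CalibrationTable:
    """Ordered (raw reading, force in N) pairs defining a monotone map."""

    raw: np.ndarray
    newton: np.ndarray

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        newton = np.asarray(self.newton, dtype=float)
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "newton", newton)
        if raw.size != newton.size or raw.size < 2:
            raise ValueError("calibration table needs >= 2 (raw, newton) pairs")
        if not np.all(np.diff(raw) > 0):
            raise ValueError("calibration raw values must be strictly increasing")
        if np.any(newton < 0) or np.any(np.diff(newton) < 0):
            raise ValueError("calibration forces must be non-negative and non-decreasing")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "CalibrationTable":
        data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        if data.shape[1] != 2:
            raise ValueError("calibration CSV must have exactly two columns")
        return cls(raw=data[:, 0], newton=data[:, 1])

    def to_csv(self, path: Union[str, Path]) -> None:
        np.savetxt(path, np.column_stack([self.raw, self.newton]),
                   delimiter=",", header="raw,newton", comments="# ")


def write_trace(trace: ForceTrace, path: Union[str, Path]) -> None:
    """Write a trace as TSV with ``#``-prefixed header lines."""
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz: {trace.sample_rate_hz!r}\n")
        fh.write(f"# units: {trace.units}\n")
        fh.write(f"# recording_id: {trace.recording_id}\n")
        fh.write(f"# t0_ms: {trace.t0_ms!r}\n")
        fh.write("# channels: force\n")
        np.savetxt(fh, trace.samples, fmt="%.9g")


def read_trace(path: Union[str, Path]) -> ForceTrace:
    """Read a trace written by :func:`write_trace`.

    Raises
    ------
    TraceFormatError
        On a missing/invalid header field or a non-numeric sample; the
        error message names the offending line.
    """
    header: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                key, _, value = stripped.lstrip("#").partition(":")
                header[key.strip()] = value.strip()
            else:
                try:
                    float(stripped.split()[0])
                except ValueError as exc:
                    raise TraceFormatError(
                        f"{path}: non-numeric sample on line {lineno}: {stripped!r}"
                    ) from exc
                body.write(stripped.split()[0] + "\n")
    for required in ("sample_rate_hz", "units"):
        if required not in header:
            raise TraceFormatError(f"{path}: missing required header field '{required}'")
    data = body.getvalue()
    if not data:
        raise TraceFormatError(f"{path}: file contains no samples")
    samples = np.loadtxt(io.StringIO(data))
    return ForceTrace(
        samples=np.atleast_1d(samples),
        sample_rate_hz=float(header["sample_rate_hz"]),
        units=header["units"],
        recording_id=header.get("recording_id", ""),
        t0_ms=float(header.get("t0_ms", 0.0)),
    )


def calibrate(trace: ForceTrace, table: CalibrationTable) -> ForceTrace:
    """Convert a raw trace to Newtons via piecewise-linear interpolation.

    Readings outside the table's raw range are clamped to the end forces.
    Calibration is applied once: the input must be in raw units.
    """
    if trace.units != "raw":
        raise TraceFormatError("calibrate expects a trace in raw units")
    forces = np.interp(trace.samples, table.raw, table.newton)
    return replace(trace, samples=forces, units="newton")


def trim_edges(trace: ForceTrace, trim_s: float = 0.5) -> ForceTrace:
    """Discard ``trim_s`` seconds from each end of the recording.

    The retained block's time origin (``t0_ms``) is advanced so that
    landmark times remain in original-recording coordinates.
    """
    if trim_s < 0:
        raise ValueError("trim_s must be non-negative")
    n_trim = int(np.floor(trim_s * trace.sample_rate_hz))
    if n_trim == 0:
        return trace
    if len(trace) <= 2 * n_trim:
        raise TraceFormatError(
            f"trace of {len(trace)} samples too short to trim {n_trim} from each end"
        )
    return replace(
        trace,
        samples=trace.samples[n_trim:-n_trim],
        t0_ms=trace.t0_ms + n_trim * 1000.0 / trace.sample_rate_hz,
    )


def smooth_bartlett(trace: ForceTrace, window_samples: int = 160) -> ForceTrace:
    """Smooth the force channel with a unit-sum triangular window.

    The kernel is centred and edges are handled by reflection, so output
    length equals input length and constant signals are fixed points.
    The triangular window has nonzero endpoints (``scipy.signal.windows.
    triang``): the 3-sample kernel is {0.25, 0.5, 0.25}.
    """
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    if window_samples > len(trace):
        raise TraceFormatError(
            f"window of {window_samples} samples longer than trace of {len(trace)}"
        )
    if window_samples == 1:
        return trace
    kernel = triang(window_samples)
    kernel /= kernel.sum()
    smoothed = convolve1d(trace.samples, kernel, mode="reflect")
    return replace(trace, samples=smoothed)


def preprocess(
    trace: ForceTrace,
    table: CalibrationTable | None = None,
    trim_s: float = 0.5,
    window_samples: int = 160,
) -> ForceTrace:
    """Full preprocessing chain: trim → calibrate → smooth.

    ``table`` may be omitted when the trace is already in Newtons (e.g.
    synthetic traces generated directly in physical units).
    """
    out = trim_edges(trace, trim_s=trim_s)
    if out.units == "raw":
        if table is None:
            raise TraceFormatError("raw trace requires a calibration table")
        out = calibrate(out, table)
    return smooth_bartlett(out, window_samples=window_samples)
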