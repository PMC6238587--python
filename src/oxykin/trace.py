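"""Core data model and text I/O for oxygen-electrode traces.

A trace is a pair of equal-length arrays (time in s, [O2] in uM) plus assay
metadata and an append-only log of the processing steps applied to it.
Traces are stored as two-column delimited text (CSV or TSV, auto-detected on
read) with a YAML sidecar carrying the metadata; the reader also accepts
``# key: value`` comment headers embedded in the trace file itself, since
electrode software exports heterogeneous text formats.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = ["AssayMetadata", "OxygenTrace", "RateSeries", "read_trace", "write_trace"]


@dataclass
class AssayMetadata:
    """Per-run assay context.

    All concentrations in uM except ``gsh_conc`` (mM); times in seconds;
    temperature in degrees C.  ``injection_time`` may be None when the
    injection point is unknown and must be detected from the trace.
    """

    enzyme_conc: float | None = None
    substrate_label: str = ""
    substrate_conc: float | None = None
    gsh_conc: float | None = None
    injection_time: float | None = None
    temperature: float = 25.0
    sample_interval: float | None = None

    def __post_init__(self) -> None:
        if self.enzyme_conc is not None and self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive when given")
        if self.sample_interval is not None and self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.injection_time is not None and self.injection_time < 0:
            raise ValueError("injection_time must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AssayMetadata":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class OxygenTrace:
    """A time series of dissolved oxygen concentration.

    Invariants: equal-length arrays of at least 3 points; strictly increasing
    times.  Processing functions return new traces and append to
    ``processing_log``; raw inputs are never mutated.
    """

    times: np.ndarray
    oxygen: np.ndarray
    metadata: AssayMetadata = field(default_factory=AssayMetadata)
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.oxygen = np.asarray(self.oxygen, dtype=float)
        if self.times.ndim != 1 or self.oxygen.ndim != 1:
            raise ValueError("times and oxygen must be 1-D arrays")
        if len(self.times) != len(self.oxygen):
            raise ValueError("times and oxygen must have equal length")
        if len(self.times) < 3:
            raise ValueError("trace must contain at least 3 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def sample_interval(self) -> float:
        """Median sampling interval (s); metadata value takes precedence."""
        if self.metadata.sample_interval is not None:
            return self.metadata.sample_interval
        return float(np.median(np.diff(self.times)))

    def with_oxygen(self, oxygen: np.ndarray, log_entry: str) -> "OxygenTrace":
        """New trace with replaced oxygen values and an appended log entry."""
        return OxygenTrace(
            times=self.times.copy(),
            oxygen=np.asarray(oxygen, dtype=float),
            metadata=replace(self.metadata),
            processing_log=[*self.processing_log, log_entry],
        )


@dataclass
class RateSeries:
    """Differentiated trace: (time, [O2], consumption rate) triplets.

    ``rate`` is the positive consumption rate -d[O2]/dt in uM/s.  ``mask``
    marks points usable for fitting: pre-injection points and the first 20 s
    after injection (mixing artifacts) are excluded.
    """

    times: np.ndarray
    oxygen: np.ndarray
    rate: np.ndarray
    mask: np.ndarray
    metadata: AssayMetadata = field(default_factory=AssayMetadata)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.oxygen = np.asarray(self.oxygen, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.times)
        if not (len(self.oxygen) == len(self.rate) == len(self.mask) == n):
            raise ValueError("all RateSeries arrays must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def masked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(times, oxygen, rate) restricted to fit-eligible points."""
        m = self.mask
        return self.times[m], self.oxygen[m], self.rate[m]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def read_trace(path, metadata: AssayMetadata | str | Path | None = None) -> OxygenTrace:
    """Read a two-column (time, oxygen) delimited text file.

    The delimiter (comma, tab or whitespace) is auto-detected and an optional
    single header line is skipped.  Metadata comes from, in order of
    precedence: an ``AssayMetadata`` passed directly, an explicit sidecar
    path, ``# key: value`` comment lines in the file, or the default sidecar
    ``<path>.meta.yaml`` when it exists.
    """
    path = Path(path)
    comment_meta: dict = {}
    times, oxygen = [], []
    seen_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    try:
                        comment_meta[key.strip()] = yaml.safe_load(val.strip())
                    except yaml.YAMLError:
                        pass
                continue
            for delim in (",", "\t", None):
                fields = line.split(delim)
                if len(fields) >= 2:
                    break
            try:
                t, o = float(fields[0]), float(fields[1])
            except (ValueError, IndexError):
                if not seen_data:
                    continue  # column-header line
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            seen_data = True
            times.append(t)
            oxygen.append(o)

    if isinstance(metadata, AssayMetadata):
        meta = metadata
    elif metadata is not None:
        with open(metadata) as fh:
            meta = AssayMetadata.from_dict(yaml.safe_load(fh) or {})
    elif _sidecar_path(path).exists():
        with open(_sidecar_path(path)) as fh:
            meta = AssayMetadata.from_dict(yaml.safe_load(fh) or {})
    else:
        meta = AssayMetadata.from_dict(comment_meta)

    try:
        return OxygenTrace(np.array(times), np.array(oxygen), metadata=meta,
                           processing_log=[f"read_trace({path.name})"])
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_trace(trace: OxygenTrace, path) -> None:
    """Write a trace as CSV plus a ``<path>.meta.yaml`` metadata sidecar.

    Floats are written with 17 significant digits, so a read/write round trip
    reproduces the arrays bit-exactly.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write("time_s,oxygen_uM\n")
    for t, o in zip(trace.times, trace.oxygen):
        buf.write(f"{t:.17g},{o:.17g}\n")
    path.write_text(buf.getvalue())
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(trace.metadata.to_dict(), fh, sort_keys=True)
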