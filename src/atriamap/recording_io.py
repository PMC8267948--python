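"""On-disk formats and in-memory containers for multichannel electrogram recordings.

A recording is stored as a plain-text delimited table preceded by ``#``-prefixed
``key=value`` header lines.  Column 1 is ``time_ms``; the remaining columns are the
bipolar channels named ``r{row}c{col}`` (1-based) in row-major order.  The stimulus
log travels in an adjacent JSON sidecar (``<stem>.stim.json``) and, for synthetic
recordings, a ground-truth sidecar (``<stem>.truth.json``) carries per-channel
activation times and restitution values for recovery tests.

Times are milliseconds and voltages millivolts throughout.  Channel indices are
0-based in memory and 1-based in file column names.
"""

from __future__ import annotations

import dataclasses
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError

FORMAT_VERSION = "1"

#: header keys every recording file must carry
REQUIRED_HEADER_KEYS = (
    "format_version",
    "rows",
    "cols",
    "spacing_mm",
    "sampling_rate_hz",
    "band_low_hz",
    "band_high_hz",
)

STIM_CORNERS = ("LAA", "LAFW")


@dataclass(frozen=True)
class ElectrodeGrid:
    """Geometry of a regular recording grid.

    The 36-unipolar-electrode plaque (0.5 mm pitch) is represented by its 25
    bipolar channels laid out as a 5x5 virtual grid, each bipole sitting at the
    centroid of a unipolar pair.
    """

    rows: int = 5
    cols: int = 5
    spacing_mm: float = 0.5
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise InvalidParameterError("grid needs at least 2 rows and 2 columns")
        if self.spacing_mm <= 0:
            raise InvalidParameterError("electrode spacing must be positive")

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def channel_name(self, row: int, col: int) -> str:
        return f"r{row + 1}c{col + 1}"

    def channel_names(self) -> list[str]:
        return [self.channel_name(r, c) for r in range(self.rows) for c in range(self.cols)]

    def positions_mm(self) -> np.ndarray:
        """(n_channels, 2) array of (x, y) positions, row-major; x runs along columns."""
        x0, y0 = self.origin_mm
        cols = np.arange(self.cols) * self.spacing_mm + x0
        rows = np.arange(self.rows) * self.spacing_mm + y0
        xx, yy = np.meshgrid(cols, rows)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def bounds_mm(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the electrode footprint."""
        x0, y0 = self.origin_mm
        return (x0, y0, x0 + (self.cols - 1) * self.spacing_mm, y0 + (self.rows - 1) * self.spacing_mm)


@dataclass(frozen=True)
class StimulusEvent:
    """One delivered stimulus: drive-train beat (S1) or premature extrastimulus (S2)."""

    t_ms: float
    kind: str  # "S1" | "S2"
    corner: str  # "LAA" | "LAFW"
    ci_ms: float | None = None  # S2 coupling interval
    cl_ms: float | None = None  # drive-train cycle length
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("S1", "S2"):
            raise InvalidParameterError(f"unknown stimulus kind {self.kind!r}")
        if self.corner not in STIM_CORNERS:
            raise InvalidParameterError(f"unknown stimulation corner {self.corner!r}")

    def to_dict(self) -> dict:
        return {
            "t_ms": self.t_ms,
            "type": self.kind,
            "ci_ms": self.ci_ms,
            "corner": self.corner,
            "cl_ms": self.cl_ms,
            "replicate": self.replicate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusEvent":
        return cls(
            t_ms=float(d["t_ms"]),
            kind=str(d["type"]),
            corner=str(d["corner"]),
            ci_ms=None if d.get("ci_ms") is None else float(d["ci_ms"]),
            cl_ms=None if d.get("cl_ms") is None else float(d["cl_ms"]),
            replicate=None if d.get("replicate") is None else int(d["replicate"]),
        )


@dataclass
class StimulusLog:
    """Ordered record of every delivered stimulus."""

    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.t_ms for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidParameterError("stimulus times must be strictly increasing")
        seen_s1 = False
        for e in self.events:
            if e.kind == "S1":
                seen_s1 = True
            elif not seen_s1:
                raise InvalidParameterError("every S2 must follow at least one S1")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def to_json_obj(self) -> list[dict]:
        return [e.to_dict() for e in self.events]

    @classmethod
    def from_json_obj(cls, obj: Iterable[dict]) -> "StimulusLog":
        return cls(events=[StimulusEvent.from_dict(d) for d in obj])


@dataclass
class Recording:
    """Time-aligned multichannel electrogram traces plus stimulus metadata.

    ``traces`` has shape ``(n_channels, n_samples)`` in row-major channel order.
    """

    grid: ElectrodeGrid
    sampling_rate_hz: float
    traces: np.ndarray
    stimulus_log: StimulusLog = field(default_factory=StimulusLog)
    band_hz: tuple[float, float] = (10.0, 500.0)
    truth: dict | None = None  # synthetic ground truth, not persisted in the table

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if self.traces.ndim != 2 or self.traces.shape[0] != self.grid.n_channels:
            raise InvalidParameterError(
                f"traces must be (n_channels={self.grid.n_channels}, n_samples); got {self.traces.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def channel(self, row: int, col: int) -> np.ndarray:
        return self.traces[row * self.grid.cols + col]


# ---------------------------------------------------------------------------
# recording file I/O
# ---------------------------------------------------------------------------

_CHANNEL_RE = re.compile(r"^r(\d+)c(\d+)$")


def _sidecar_path(path: Path, tag: str) -> Path:
    return path.with_name(path.stem + f".{tag}.json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` to a '#'-headed delimited text file; the stimulus log goes to an
    adjacent ``.stim.json`` sidecar and any synthetic ground truth to ``.truth.json``.
    """
    path = Path(path)
    g = rec.grid
    header = {
        "format_version": FORMAT_VERSION,
        "rows": g.rows,
        "cols": g.cols,
        "spacing_mm": _fmt(g.spacing_mm),
        "sampling_rate_hz": _fmt(rec.sampling_rate_hz),
        "band_low_hz": _fmt(rec.band_hz[0]),
        "band_high_hz": _fmt(rec.band_hz[1]),
        "origin_x_mm": _fmt(g.origin_mm[0]),
        "origin_y_mm": _fmt(g.origin_mm[1]),
    }
    buf = io.StringIO()
    for k, v in header.items():
        buf.write(f"# {k}={v}\n")
    table = pd.DataFrame(rec.traces.T, columns=g.channel_names())
    table.insert(0, "time_ms", rec.time_ms())
    table.to_csv(buf, index=False, float_format="%.6g")
    path.write_text(buf.getvalue())
    _sidecar_path(path, "stim").write_text(
        json.dumps({"events": rec.stimulus_log.to_json_obj()}, indent=1)
    )
    if rec.truth is not None:
        _sidecar_path(path, "truth").write_text(json.dumps(rec.truth, indent=1, sort_keys=True))
    return path


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


def _parse_header(lines: list[str]) -> dict[str, str]:
    header: dict[str, str] = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" in body:
            k, v = body.split("=", 1)
            header[k.strip()] = v.strip()
    return header


def read_recording(path: str | Path) -> Recording:
    """Read a recording file written by :func:`write_recording`.

    Channel ordering is reconstructed from the ``r{row}c{col}`` column names, never
    from column position.  Malformed files are rejected, not repaired.
    """
    path = Path(path)
    text = path.read_text()
    header_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    header = _parse_header(header_lines)
    for key in REQUIRED_HEADER_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing header key '{key}'")
    try:
        table = pd.read_csv(io.StringIO(text), comment="#")
    except pd.errors.ParserError as exc:  # ragged rows: pandas message carries the line
        raise FormatError(f"{path}: malformed table ({exc})") from exc
    if "time_ms" not in table.columns:
        raise FormatError(f"{path}: missing 'time_ms' column")
    if table.isna().any().any():
        bad = int(table.isna().any(axis=1).idxmax()) + 2  # +1 header row, +1 1-based
        raise FormatError(f"{path}: ragged or non-numeric table near data line {bad}")

    rows, cols = int(header["rows"]), int(header["cols"])
    origin = (float(header.get("origin_x_mm", 0.0)), float(header.get("origin_y_mm", 0.0)))
    grid = ElectrodeGrid(rows=rows, cols=cols, spacing_mm=float(header["spacing_mm"]), origin_mm=origin)
    expected = set(grid.channel_names())
    present = set(table.columns) - {"time_ms"}
    if present != expected:
        missing = sorted(expected - present)
        extra = sorted(present - expected)
        raise FormatError(f"{path}: channel columns mismatch (missing={missing}, unexpected={extra})")
    traces = np.stack([table[name].to_numpy(dtype=float) for name in grid.channel_names()])

    stim_path = _sidecar_path(path, "stim")
    log = StimulusLog()
    if stim_path.exists():
        log = StimulusLog.from_json_obj(json.loads(stim_path.read_text())["events"])
    truth_path = _sidecar_path(path, "truth")
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None

    return Recording(
        grid=grid,
        sampling_rate_hz=float(header["sampling_rate_hz"]),
        traces=traces,
        stimulus_log=log,
        band_hz=(float(header["band_low_hz"]), float(header["band_high_hz"])),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# activation-map CSV export
# ---------------------------------------------------------------------------

def write_activation_map_csv(amap, path: str | Path) -> Path:
    """Export an activation map as CSV with columns row, col, x_mm, y_mm, lat_ms.

    Unannotated channels get an empty ``lat_ms`` field.
    """
    path = Path(path)
    g = amap.grid
    pos = g.positions_mm()
    records = []
    for r in range(g.rows):
        for c in range(g.cols):
            lat = amap.lat_ms[r, c]
            records.append(
                {
                    "row": r,
                    "col": c,
                    "x_mm": pos[r * g.cols + c, 0],
                    "y_mm": pos[r * g.cols + c, 1],
                    "lat_ms": "" if np.isnan(lat) else format(lat, ".6g"),
                }
            )
    pd.DataFrame(records).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# single-channel action-potential trace files (same header format, column "ap")
# ---------------------------------------------------------------------------

def write_ap_trace(trace, path: str | Path) -> Path:
    """Write an intracellular action-potential trace using the recording format
    with a single channel column named ``ap``."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# format_version={FORMAT_VERSION}\n")
    buf.write(f"# sampling_rate_hz={_fmt(trace.sampling_rate_hz)}\n")
    table = pd.DataFrame({"time_ms": trace.time_ms, "ap": trace.voltage_mv})
    table.to_csv(buf, index=False, float_format="%.6g")
    path.write_text(buf.getvalue())
    return path


def read_ap_trace(path: str | Path):
    from .cellular_metrics import APTrace  # local import to avoid a cycle

    path = Path(path)
    text = path.read_text()
    header = _parse_header([ln for ln in text.splitlines() if ln.startswith("#")])
    if "sampling_rate_hz" not in header:
        raise FormatError(f"{path}: missing header key 'sampling_rate_hz'")
    table = pd.read_csv(io.StringIO(text), comment="#")
    if "ap" not in table.columns:
        raise FormatError(f"{path}: missing 'ap' column")
    return APTrace(
        voltage_mv=table["ap"].to_numpy(dtype=float),
        sampling_rate_hz=float(header["sampling_rate_hz"]),
    )
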