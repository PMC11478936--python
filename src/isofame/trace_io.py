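"""Readers and writers for every on-disk artifact, plus the run configuration.

The trace format is a plain-text dialect: a ``# key: value`` header block
followed by a CSV body with columns ``time_s,i2_mV,i3_mV`` (time may instead
be declared in minutes via the units header and is converted to seconds on
read).  Vendor IRMS formats are proprietary; this documented open dialect
keeps every stage of the pipeline testable.
"""

from __future__ import annotations

import dataclasses
import io
import json
import os
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParseError",
    "ConfigError",
    "IsotopeTrace",
    "LibraryEntry",
    "CompoundLibrary",
    "read_trace",
    "write_trace",
    "read_library",
    "write_library",
    "read_anchors",
    "PeakSettings",
    "BackgroundSettings",
    "IdentifySettings",
    "CalibrateSettings",
    "RunConfig",
    "load_config",
    "write_results",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ConfigError(ValueError):
    """A run configuration failed validation."""


# --------------------------------------------------------------------------
# in-memory containers


@dataclass
class IsotopeTrace:
    """Time-aligned mass-2 / mass-3 ion-current series for one injection.

    time is in seconds (strictly increasing), intensities in mV.  ``meta``
    carries run metadata (sample id, injection volume, run index, reference
    pulse windows, ...).
    """

    time: np.ndarray
    i2: np.ndarray
    i3: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.i2 = np.asarray(self.i2, dtype=float)
        self.i3 = np.asarray(self.i3, dtype=float)
        if not (len(self.time) == len(self.i2) == len(self.i3)):
            raise ValueError("time, i2 and i3 must have equal lengths")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        for name, arr in (("time", self.time), ("i2", self.i2), ("i3", self.i3)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        """Median sampling interval, s."""
        return float(np.median(np.diff(self.time)))

    def with_i3(self, i3: np.ndarray) -> "IsotopeTrace":
        """Copy of this trace with a replaced mass-3 series."""
        return IsotopeTrace(self.time.copy(), self.i2.copy(), np.asarray(i3, float), dict(self.meta))

    def window_slice(self, t_start: float, t_end: float) -> slice:
        """Index slice covering [t_start, t_end] inclusive."""
        i0 = int(np.searchsorted(self.time, t_start, side="left"))
        i1 = int(np.searchsorted(self.time, t_end, side="right"))
        return slice(i0, i1)


@dataclass(frozen=True)
class LibraryEntry:
    name: str
    h_n: int          # H atoms of the free fatty acid
    rt: float         # expected retention time, s
    fa_class: str = ""  # SFA / MUFA / n-3 / n-6


@dataclass
class CompoundLibrary:
    """Retention-time library of fatty-acid methyl esters."""

    entries: list[LibraryEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("library compound names must be unique")
        for e in self.entries:
            if e.h_n < 4:
                raise ValueError(f"{e.name}: H count {e.h_n} < 4 is not a valid fatty acid")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> LibraryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]


# --------------------------------------------------------------------------
# trace file format

_TIME_COLUMNS = {"time_s": 1.0, "time_min": 60.0}
_FMT = "%.6g"  # declared round-trip precision: 6 significant digits


def write_trace(trace: IsotopeTrace, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for key, value in trace.meta.items():
            encoded = value if isinstance(value, str) else json.dumps(value)
            fh.write(f"# {key}: {encoded}\n")
        fh.write("# units: time=s,intensity=mV\n")
        fh.write("time_s,i2_mV,i3_mV\n")
        for t, a, b in zip(trace.time, trace.i2, trace.i3):
            fh.write(f"{_FMT % t},{_FMT % a},{_FMT % b}\n")


def _parse_meta_value(raw: str) -> Any:
    try:
        return json.loads(raw)
    except (json.JSONDecodeError, ValueError):
        return raw


def read_trace(path: str | os.PathLike) -> IsotopeTrace:
    meta: dict[str, Any] = {}
    time_scale = None
    rows: list[tuple[float, float, float]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, raw = body.partition(":")
                    key, raw = key.strip(), raw.strip()
                    if key == "units":
                        continue  # units are taken from the column header
                    meta[key] = _parse_meta_value(raw)
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if len(cols) != 3 or cols[1] != "i2_mV" or cols[2] != "i3_mV":
                    raise ParseError(
                        f"{path}: line {lineno}: expected header 'time_s,i2_mV,i3_mV', got {line!r}"
                    )
                if cols[0] not in _TIME_COLUMNS:
                    raise ParseError(
                        f"{path}: line {lineno}: unknown time column/unit {cols[0]!r}"
                    )
                time_scale = _TIME_COLUMNS[cols[0]]
                header_seen = True
                continue
            fields = line.split(",")
            if len(fields) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 comma-separated values, got {len(fields)}"
                )
            try:
                rows.append((float(fields[0]), float(fields[1]), float(fields[2])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    if not header_seen:
        raise ParseError(f"{path}: missing column header line")
    if not rows:
        raise ParseError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    time = arr[:, 0] * time_scale
    if len(time) > 1 and not np.all(np.diff(time) > 0):
        bad = int(np.argmax(np.diff(time) <= 0))
        raise ParseError(f"{path}: time not strictly increasing near data row {bad + 2}")
    try:
        return IsotopeTrace(time, arr[:, 1], arr[:, 2], meta)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


# --------------------------------------------------------------------------
# library / anchors tables


def write_library(library: CompoundLibrary, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(e.name, e.h_n, e.rt, e.fa_class) for e in library],
        columns=["name", "h_n", "rt_s", "class"],
    )
    df.to_csv(path, index=False)


def read_library(path: str | os.PathLike) -> CompoundLibrary:
    df = pd.read_csv(path)
    required = {"name", "h_n", "rt_s"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    entries = [
        LibraryEntry(
            name=str(r["name"]),
            h_n=int(r["h_n"]),
            rt=float(r["rt_s"]),
            fa_class=str(r.get("class", "")) if "class" in df.columns else "",
        )
        for _, r in df.iterrows()
    ]
    try:
        return CompoundLibrary(entries)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def read_anchors(path: str | os.PathLike) -> list[dict]:
    """Anchors table: name, assigned_delta (per mil), u (per mil)."""
    df = pd.read_csv(path)
    missing = {"name", "assigned_delta", "u"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        {"name": str(r["name"]), "assigned_delta": float(r["assigned_delta"]), "u": float(r["u"])}
        for _, r in df.iterrows()
    ]


def write_results(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """Results table; delta columns rounded to the reported 0.1 per-mil precision."""
    out = results.copy()
    for col in ("delta_fame", "delta_fa", "u_total"):
        if col in out.columns:
            out[col] = out[col].round(1)
    out.to_csv(path, index=False)


# --------------------------------------------------------------------------
# run configuration


@dataclass
class PeakSettings:
    start_slope: float = 1.0      # mV/s, sustained-rise threshold marking peak start
    end_slope: float = 0.5        # mV/s, tail-flattening threshold marking peak end
    min_amplitude: float = 450.0  # mV, QC gate on background-subtracted amplitude
    min_area: float = 4.0         # V*s, QC gate on mass-2 area
    sg_window: int = 21           # samples, local-polynomial derivative window
    sg_poly: int = 2

    def validate(self) -> None:
        if self.start_slope <= 0 or self.end_slope <= 0:
            raise ConfigError("peak slope thresholds must be positive")
        if self.min_amplitude < 0 or self.min_area < 0:
            raise ConfigError("QC thresholds must be non-negative")
        if self.sg_window < 5 or self.sg_window % 2 == 0:
            raise ConfigError("sg_window must be an odd integer >= 5")
        if self.sg_poly < 1 or self.sg_poly >= self.sg_window:
            raise ConfigError("sg_poly must satisfy 1 <= sg_poly < sg_window")


_DEFAULT_STEP = {"dynamic": 150.0, "basefit": 200.0}


@dataclass
class BackgroundSettings:
    mode: str = "dynamic"             # individual | dynamic | basefit
    step_width: float | None = None   # s; defaults: dynamic 150, basefit 200
    smoothing: float | None = None    # basefit spline stiffness; must be explicit
    history_time: float | None = None # s; individual mode look-back (no default)
    # 2nd-percentile step statistic instead of strict minimum; None = decide
    # per trace from its declared noise level
    robust: bool | None = None

    def validate(self) -> None:
        if self.mode not in ("individual", "dynamic", "basefit"):
            raise ConfigError(f"unknown background mode {self.mode!r}")
        if self.step_width is None and self.mode in _DEFAULT_STEP:
            self.step_width = _DEFAULT_STEP[self.mode]
        if self.step_width is not None and self.step_width <= 0:
            raise ConfigError("background step_width must be positive")
        if self.mode == "basefit" and self.smoothing is None:
            raise ConfigError(
                "basefit background requires an explicit 'smoothing' factor; "
                "it must be tuned per instrument setup"
            )
        if self.smoothing is not None and self.smoothing <= 0:
            raise ConfigError("smoothing must be positive")
        if self.mode == "individual":
            if self.history_time is None:
                raise ConfigError("individual background requires an explicit history_time")
            if self.history_time <= 0:
                raise ConfigError("history_time must be positive")


@dataclass
class IdentifySettings:
    tolerance: float = 10.0                      # s, RT match window
    merge: list[list[str]] = field(default_factory=list)  # coelution merge groups

    def validate(self) -> None:
        if self.tolerance <= 0:
            raise ConfigError("identify tolerance must be positive")
        for group in self.merge:
            if len(group) < 2:
                raise ConfigError("each merge rule must name at least 2 compounds")


@dataclass
class CalibrateSettings:
    anchors: list[dict] = field(
        default_factory=lambda: [
            {"name": "USGS70", "assigned_delta": -183.9, "u": 1.4},
            {"name": "USGS71", "assigned_delta": -4.9, "u": 1.0},
        ]
    )
    methanol_delta: float = -146.8   # per mil vs VSMOW, transmethylation reagent
    methanol_u: float = 2.6          # per mil
    include_methanol_u: bool = False # optional fifth quadrature component
    u_vsmow: float = 0.3             # per mil, VSMOW2 assignment uncertainty
    ref_delta: float = -120.0        # per mil, assigned value of the H2 reference gas
    h3_factor: float | None = None   # ppm/V; if None it must be estimated from a dilution series
    replicate_sd: float = 0.0        # per mil, SD of replicated control samples

    def validate(self) -> None:
        if len(self.anchors) != 2:
            raise ConfigError("two-point normalization needs exactly 2 anchors")
        for a in self.anchors:
            if not {"name", "assigned_delta", "u"} <= set(a):
                raise ConfigError("each anchor needs name, assigned_delta and u")
        for name, val in (
            ("methanol_u", self.methanol_u),
            ("u_vsmow", self.u_vsmow),
            ("replicate_sd", self.replicate_sd),
        ):
            if val < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.h3_factor is not None and self.h3_factor < 0:
            raise ConfigError("h3_factor must be non-negative")


@dataclass
class RunConfig:
    peaks: PeakSettings = field(default_factory=PeakSettings)
    background: BackgroundSettings = field(default_factory=BackgroundSettings)
    identify: IdentifySettings = field(default_factory=IdentifySettings)
    calibrate: CalibrateSettings = field(default_factory=CalibrateSettings)

    def validate(self) -> "RunConfig":
        self.peaks.validate()
        self.background.validate()
        self.identify.validate()
        self.calibrate.validate()
        return self


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | os.PathLike | None = None, text: str | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty (or absent) configuration yields the published defaults: start
    slope 1 mV/s, end slope 0.5 mV/s, QC gates 450 mV / 4 V*s, dynamic step
    150 s, basefit step 200 s.  Unknown keys are rejected.
    """
    if text is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    else:
        data = yaml.safe_load(io.StringIO(text)) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    sections = {"peaks": PeakSettings, "background": BackgroundSettings,
                "identify": IdentifySettings, "calibrate": CalibrateSettings}
    unknown = set(data) - set(sections)
    if unknown:
        raise ConfigError(f"unknown configuration section(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        kwargs[name] = _build_section(cls, data.get(name, {}) or {}, name)
    return RunConfig(**kwargs).validate()
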