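"""Domain containers and tabular I/O for recording sessions.

The pipeline exchanges three kinds of tables: single-cell calcium traces
(one row per cell, one column per frame), behavioral zone tracking (one row
per tracking sample) and small summary tables.  Everything is plain UTF-8
CSV with '.' decimals and a header row, matching common miniscope/tracking
exports, so files round-trip exactly and diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CellTraceSet",
    "ZoneOccupancy",
    "EventList",
    "FormatError",
    "read_trace_table",
    "write_trace_table",
    "read_tracking_table",
    "write_tracking_table",
    "align_to_trace_clock",
    "PipelineConfig",
    "load_config",
    "dump_config",
    "provenance_record",
]


class FormatError(ValueError):
    """A file violated the documented dialect; message names the location."""


@dataclass
class CellTraceSet:
    """Cells x frames activity matrix for one recording session."""

    values: np.ndarray  # (n_cells, n_frames)
    rate: float  # frames / s
    cell_ids: list[str]
    animal_id: str = ""
    session_id: str = ""
    t0: float = 0.0
    registration_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x frames matrix")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length must match number of rows")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique within a session")
        if np.isnan(self.values).any():
            raise ValueError("trace matrix contains missing values")
        if self.registration_ids is not None:
            if len(self.registration_ids) != self.values.shape[0]:
                raise ValueError("registration_ids length must match cells")
            nonempty = [r for r in self.registration_ids if r]
            if len(set(nonempty)) != len(nonempty):
                raise ValueError("registration_ids must be unique when present")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate

    def frame_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.rate

    def zscored(self) -> "CellTraceSet":
        """Per-cell z-score across the whole session (sample s.d., ddof=1)."""
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant trace cannot be z-scored")
        return CellTraceSet(
            values=(self.values - mu) / sd,
            rate=self.rate,
            cell_ids=list(self.cell_ids),
            animal_id=self.animal_id,
            session_id=self.session_id,
            t0=self.t0,
            registration_ids=(
                list(self.registration_ids) if self.registration_ids else None
            ),
        )


@dataclass
class ZoneOccupancy:
    """One-hot zone indicators on the tracking clock.

    indicators is zones x samples with entries in {0, 1}; zones are mutually
    exclusive so column sums never exceed 1 (unassigned samples are all-zero,
    e.g. while the animal transits between zones).
    """

    zones: list[str]
    indicators: np.ndarray  # (n_zones, n_samples) of 0/1
    rate: float  # samples / s
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators)
        if self.indicators.ndim != 2:
            raise ValueError("indicators must be zones x samples")
        if len(self.zones) != self.indicators.shape[0]:
            raise ValueError("zone names must match indicator rows")
        if len(set(self.zones)) != len(self.zones):
            raise ValueError("zone names must be unique")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        vals = np.unique(self.indicators)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("indicators must be binary")
        sums = self.indicators.sum(axis=0)
        if np.any(sums > 1):
            bad = np.flatnonzero(sums > 1)
            times = (self.t0 + bad / self.rate)[:5]
            raise ValueError(
                "zones overlap (column sum > 1) at t = "
                + ", ".join(f"{t:.3f}s" for t in times)
            )
        self.indicators = self.indicators.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.indicators.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def sample_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def indicator(self, zone: str) -> np.ndarray:
        return self.indicators[self.zones.index(zone)]


@dataclass
class EventList:
    """Ordered zone entry/exit times in seconds, per zone.

    Per zone, entries are strictly increasing, each exit follows its entry
    and visit intervals do not overlap.
    """

    entries: dict[str, np.ndarray] = field(default_factory=dict)
    exits: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for zone in self.entries:
            ent = np.asarray(self.entries[zone], dtype=float)
            ext = np.asarray(self.exits.get(zone, []), dtype=float)
            if ent.size != ext.size:
                raise ValueError(f"zone {zone!r}: entry/exit counts differ")
            if ent.size and np.any(np.diff(ent) <= 0):
                raise ValueError(f"zone {zone!r}: entries not strictly increasing")
            if np.any(ext <= ent):
                raise ValueError(f"zone {zone!r}: exit must follow its entry")
            if ent.size > 1 and np.any(ent[1:] < ext[:-1]):
                raise ValueError(f"zone {zone!r}: overlapping visits")
            self.entries[zone] = ent
            self.exits[zone] = ext

    def n_visits(self, zone: str) -> int:
        return len(self.entries.get(zone, ()))


# ---------------------------------------------------------------------------
# trace tables


def write_trace_table(traces: CellTraceSet, path) -> None:
    """Write a CellTraceSet as CSV: cell_id, registration_id, f0, f1, ..."""
    path = Path(path)
    n = traces.n_frames
    cols = {"cell_id": traces.cell_ids}
    cols["registration_id"] = (
        traces.registration_ids
        if traces.registration_ids is not None
        else [""] * traces.n_cells
    )
    df = pd.DataFrame(cols)
    frame_cols = pd.DataFrame(
        traces.values, columns=[f"f{i}" for i in range(n)]
    )
    out = pd.concat([df, frame_cols], axis=1)
    out.to_csv(path, index=False, float_format="%.17g")


def read_trace_table(
    path,
    rate: float = 10.0,
    animal_id: str = "",
    session_id: str = "",
    t0: float = 0.0,
) -> CellTraceSet:
    """Read a trace CSV (rows = cells, frame columns f0..fN).

    Malformed numeric cells are reported with their row and column; a missing
    header or ragged rows raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header or "cell_id" not in header.split(","):
            raise FormatError(f"{path}: missing header row with 'cell_id'")
        names = header.split(",")
        ncol = len(names)
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != ncol:
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {ncol}"
                )
            rows.append(parts)
    frame_cols = [i for i, n in enumerate(names) if n.startswith("f") and n[1:].isdigit()]
    if not frame_cols:
        raise FormatError(f"{path}: no frame columns (f0, f1, ...) found")
    id_idx = names.index("cell_id")
    reg_idx = names.index("registration_id") if "registration_id" in names else None
    cell_ids, reg_ids = [], []
    values = np.empty((len(rows), len(frame_cols)), dtype=float)
    for r, parts in enumerate(rows):
        cell_ids.append(parts[id_idx])
        reg_ids.append(parts[reg_idx] if reg_idx is not None else "")
        for j, c in enumerate(frame_cols):
            cell = parts[c]
            try:
                values[r, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {cell!r} at row {r + 2}, "
                    f"column {names[c]!r}"
                ) from None
    registration = reg_ids if any(reg_ids) else None
    return CellTraceSet(
        values=values,
        rate=rate,
        cell_ids=cell_ids,
        animal_id=animal_id,
        session_id=session_id,
        t0=t0,
        registration_ids=registration,
    )


# ---------------------------------------------------------------------------
# tracking tables


def write_tracking_table(occ: ZoneOccupancy, path) -> None:
    """Write occupancy as CSV: time, then one binary column per zone."""
    df = pd.DataFrame({"time": occ.sample_times()})
    for i, z in enumerate(occ.zones):
        df[z] = occ.indicators[i]
    df.to_csv(path, index=False, float_format="%.17g")


def read_tracking_table(path, zone_defs: dict | None = None) -> ZoneOccupancy:
    """Read a tracking CSV into one-hot :class:`ZoneOccupancy`.

    Two dialects:

    * ``time`` plus one binary column per zone;
    * ``time, x, y`` plus ``zone_defs`` mapping zone name to a rectangle
      ``(x0, x1, y0, y1)``; points are assigned by half-open containment
      ``[x0, x1) x [y0, y1)`` so shared edges belong to exactly one zone.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: {e}") from e
    if "time" not in df.columns:
        raise FormatError(f"{path}: missing required 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 tracking samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column not strictly increasing")
    rate = 1.0 / float(np.median(dt))

    if {"x", "y"}.issubset(df.columns) and zone_defs:
        _check_rect_overlap(zone_defs)
        zones = list(zone_defs)
        x = df["x"].to_numpy(dtype=float)
        y = df["y"].to_numpy(dtype=float)
        ind = np.zeros((len(zones), len(t)), dtype=np.int8)
        for i, z in enumerate(zones):
            x0, x1, y0, y1 = zone_defs[z]
            ind[i] = ((x >= x0) & (x < x1) & (y >= y0) & (y < y1)).astype(np.int8)
        return ZoneOccupancy(zones=zones, indicators=ind, rate=rate, t0=float(t[0]))

    zones = [c for c in df.columns if c not in ("time", "x", "y")]
    if not zones:
        raise FormatError(f"{path}: no zone columns found")
    ind = np.zeros((len(zones), len(t)), dtype=np.int8)
    for i, z in enumerate(zones):
        col = df[z].to_numpy()
        if not np.all(np.isin(col, (0, 1))):
            bad = np.flatnonzero(~np.isin(col, (0, 1)))[0]
            raise FormatError(
                f"{path}: zone column {z!r} non-binary at row {bad + 2}"
            )
        ind[i] = col
    sums = ind.sum(axis=0)
    if np.any(sums > 1):
        bad = np.flatnonzero(sums > 1)
        stamps = ", ".join(f"{t[i]:.3f}" for i in bad[:10])
        raise FormatError(
            f"{path}: {bad.size} samples assigned to two zones at t = {stamps}"
        )
    return ZoneOccupancy(zones=zones, indicators=ind, rate=rate, t0=float(t[0]))


def _check_rect_overlap(zone_defs: dict) -> None:
    names = list(zone_defs)
    for i, a in enumerate(names):
        ax0, ax1, ay0, ay1 = zone_defs[a]
        for b in names[i + 1 :]:
            bx0, bx1, by0, by1 = zone_defs[b]
            if ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1:
                raise FormatError(f"zone rectangles {a!r} and {b!r} overlap")


def align_to_trace_clock(occ: ZoneOccupancy, trace_rate: float, n_frames: int) -> ZoneOccupancy:
    """Resample tracking occupancy onto the trace clock.

    Each frame takes the tracking sample nearest its midpoint — an explicit,
    reversible convention for reconciling the 30 Hz tracking clock with the
    10 Hz trace clock.
    """
    mid = occ.t0 + (np.arange(n_frames) + 0.5) / trace_rate
    idx = np.rint((mid - occ.t0) * occ.rate).astype(int)
    idx = np.clip(idx, 0, occ.n_samples - 1)
    return ZoneOccupancy(
        zones=list(occ.zones),
        indicators=occ.indicators[:, idx],
        rate=trace_rate,
        t0=occ.t0,
    )


# ---------------------------------------------------------------------------
# configuration

_CONFIG_DEFAULTS: dict = {
    "trim_s": 5.0,
    "artifact_window_s": 20.0,
    "artifact_k": 4.0,
    "smooth_window_s": 1.0,
    "bin_s": 1.0,
    "pre_s": 5.0,
    "post_s": 15.0,
    "min_visit_s": 1.0,
    "alpha": 0.05,
    "effect_gate": 0.0,
    "smoother_span": 0.3,
}


@dataclass(frozen=True)
class PipelineConfig:
    trim_s: float = 5.0
    artifact_window_s: float = 20.0
    artifact_k: float = 4.0
    smooth_window_s: float = 1.0
    bin_s: float = 1.0
    pre_s: float = 5.0
    post_s: float = 15.0
    min_visit_s: float = 1.0
    alpha: float = 0.05
    effect_gate: float = 0.0
    smoother_span: float = 0.3

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _CONFIG_DEFAULTS}


def load_config(path_or_dict) -> PipelineConfig:
    """Load a YAML/JSON pipeline configuration; unknown keys are rejected."""
    if isinstance(path_or_dict, dict):
        doc = dict(path_or_dict)
    else:
        text = Path(path_or_dict).read_text(encoding="utf-8")
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise FormatError(f"{path_or_dict}: config must be a mapping")
    unknown = set(doc) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_CONFIG_DEFAULTS, **doc}
    for key in ("trim_s", "artifact_window_s", "artifact_k", "smooth_window_s",
                "bin_s", "pre_s", "post_s", "min_visit_s", "smoother_span"):
        if not (float(merged[key]) >= 0):
            raise FormatError(f"config key {key}: must be >= 0, got {merged[key]}")
    if not (0.0 < float(merged["alpha"]) < 1.0):
        raise FormatError(f"config key alpha: must lie in (0, 1), got {merged['alpha']}")
    if float(merged["effect_gate"]) < 0:
        raise FormatError("config key effect_gate: must be >= 0")
    return PipelineConfig(**{k: float(v) for k, v in merged.items()})


def dump_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict()), encoding="utf-8")


# ---------------------------------------------------------------------------
# provenance


def provenance_record(operation: str, parameters: dict, seed=None, inputs: dict | None = None) -> dict:
    """One provenance entry: operation, parameters, seed and input digests."""
    digests = {}
    for name, obj in (inputs or {}).items():
        arr = np.ascontiguousarray(np.asarray(obj, dtype=float))
        digests[name] = hashlib.sha256(arr.tobytes()).hexdigest()[:16]
    return {
        "operation": operation,
        "parameters": {k: _jsonable(v) for k, v in parameters.items()},
        "seed": seed,
        "input_digests": digests,
    }


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    try:
        json.dumps(v)
        return v
    except TypeError:
        return repr(v)
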