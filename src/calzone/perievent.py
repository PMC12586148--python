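"""Peri-event quantification of zone-referenced calcium activity.

Traces are binned (1-s bins), zone entries/exits are detected from one-hot
occupancy with a debounce floor, epochs spanning -5 s to +15 s around each
entry are extracted, and responses are summarized as means over named
relative-time windows.  A local quadratic regression smoother produces the
peri-event mean curve with a pointwise s.e.m. band for visualization-style
summaries.

All windows are half-open [start, end) on relative time; the named registry
below pins the exact second-offsets used throughout the analysis:

* ``pre`` / ``post``: 3-s windows immediately before / after entry
* ``peri_entry``: -1 s to +1 s around entry
* ``post_2_4`` / ``post_4_6``: later 2-s-offset response windows
* ``approach``: -6 s to -3 s before a (manually scored) food contact
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session_io import EventList, ZoneOccupancy

__all__ = [
    "WindowSpec",
    "WINDOWS",
    "PeriEventMatrix",
    "bin_signal",
    "detect_transitions",
    "extract_epochs",
    "window_mean",
    "smooth_perievent",
]


@dataclass(frozen=True)
class WindowSpec:
    name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"window {self.name!r}: end must exceed start")


WINDOWS: dict[str, WindowSpec] = {
    w.name: w
    for w in (
        WindowSpec("pre", -3.0, 0.0),
        WindowSpec("post", 0.0, 3.0),
        WindowSpec("peri_entry", -1.0, 1.0),
        WindowSpec("post_2_4", 2.0, 4.0),
        WindowSpec("post_4_6", 4.0, 6.0),
        WindowSpec("approach", -6.0, -3.0),
    )
}


@dataclass
class PeriEventMatrix:
    """Epochs x relative-time grid of activity around zone entries."""

    values: np.ndarray  # (n_epochs, n_times); NaN where truncated
    rel_time: np.ndarray  # (n_times,) seconds relative to entry
    entry_times: np.ndarray  # (n_epochs,) absolute entry time (s)
    truncated: np.ndarray  # (n_epochs,) bool
    cell_id: str = ""
    zone: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.entry_times):
            raise ValueError("one row per entry required")
        if self.values.shape[1] != len(self.rel_time):
            raise ValueError("columns must match the relative-time grid")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


def bin_signal(trace: np.ndarray, rate: float, bin_s: float = 1.0) -> np.ndarray:
    """Non-overlapping bin means; a final partial bin is dropped."""
    x = np.asarray(trace, dtype=float)
    per_bin = bin_s * rate
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ValueError("bin_s must be a multiple of the frame period")
    per_bin = int(round(per_bin))
    if per_bin < 1:
        raise ValueError("bin shorter than one frame")
    n_bins = x.size // per_bin
    return x[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)


def detect_transitions(
    occupancy: ZoneOccupancy, min_visit_s: float = 1.0
) -> EventList:
    """Zone entries (0->1) and exits (1->0), debounced.

    Gaps shorter than ``min_visit_s`` between consecutive visits to the same
    zone are merged first (tracking flicker), then visits still shorter than
    ``min_visit_s`` are dropped.  A visit open at session end is closed at
    the session boundary.
    """
    entries: dict[str, np.ndarray] = {}
    exits: dict[str, np.ndarray] = {}
    rate = occupancy.rate
    T = occupancy.duration
    for zi, zone in enumerate(occupancy.zones):
        ind = occupancy.indicators[zi].astype(int)
        d = np.diff(np.concatenate(([0], ind, [0])))
        starts = np.flatnonzero(d == 1) / rate
        ends = np.flatnonzero(d == -1) / rate
        ends = np.minimum(ends, T)
        # merge short gaps
        if starts.size > 1 and min_visit_s > 0:
            keep_s, keep_e = [starts[0]], [ends[0]]
            for s, e in zip(starts[1:], ends[1:]):
                if s - keep_e[-1] < min_visit_s:
                    keep_e[-1] = e
                else:
                    keep_s.append(s)
                    keep_e.append(e)
            starts, ends = np.array(keep_s), np.array(keep_e)
        # drop short visits (never one that runs to session end: duration unknown)
        if min_visit_s > 0 and starts.size:
            dur = ends - starts
            ok = (dur >= min_visit_s) | (ends >= T)
            starts, ends = starts[ok], ends[ok]
        entries[zone] = starts
        exits[zone] = ends
    return EventList(entries=entries, exits=exits)


def extract_epochs(
    trace: np.ndarray,
    rate: float,
    event_times: np.ndarray,
    pre_s: float = 5.0,
    post_s: float = 15.0,
    t0: float = 0.0,
    cell_id: str = "",
    zone: str = "",
) -> PeriEventMatrix:
    """One epoch row per event, on a uniform relative-time grid at the trace
    rate.  Samples outside the session are NaN and the row is flagged
    truncated — epochs are never zero-filled."""
    x = np.asarray(trace, dtype=float)
    events = np.asarray(event_times, dtype=float)
    n_pre = int(round(pre_s * rate))
    n_post = int(round(post_s * rate))
    rel = np.arange(-n_pre, n_post + 1) / rate
    n_times = rel.size
    values = np.full((events.size, n_times), np.nan)
    truncated = np.zeros(events.size, dtype=bool)
    for r, ev in enumerate(events):
        center = int(round((ev - t0) * rate))
        idx = center + np.arange(-n_pre, n_post + 1)
        ok = (idx >= 0) & (idx < x.size)
        values[r, ok] = x[idx[ok]]
        truncated[r] = not ok.all()
    return PeriEventMatrix(
        values=values,
        rel_time=rel,
        entry_times=events,
        truncated=truncated,
        cell_id=cell_id,
        zone=zone,
    )


def window_mean(
    matrix: PeriEventMatrix, window: WindowSpec
) -> tuple[np.ndarray, float, int]:
    """Mean activity over relative time in [start, end) per epoch.

    Returns (per-epoch means, their mean across epochs, count of epochs
    excluded because truncation removed part of the window).  Epoch means
    are computed first and then averaged across epochs.
    """
    rel = matrix.rel_time
    dt = rel[1] - rel[0]
    if window.start_s < rel[0] - 1e-9 or window.end_s > rel[-1] + dt + 1e-9:
        raise ValueError(
            f"window [{window.start_s}, {window.end_s}) outside epoch range "
            f"[{rel[0]}, {rel[-1]}]"
        )
    sel = (rel >= window.start_s) & (rel < window.end_s)
    if not sel.any():
        raise ValueError("window contains no samples at this rate")
    sub = matrix.values[:, sel]
    complete = ~np.isnan(sub).any(axis=1)
    per_epoch = np.full(matrix.n_epochs, np.nan)
    per_epoch[complete] = sub[complete].mean(axis=1)
    n_excluded = int((~complete).sum())
    overall = float(per_epoch[complete].mean()) if complete.any() else float("nan")
    return per_epoch, overall, n_excluded


def smooth_perievent(
    matrix: PeriEventMatrix, span: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Local quadratic regression of pooled epoch activity vs relative time.

    Tricube-weighted quadratic fits in a window covering a ``span`` fraction
    of the epoch's time range, evaluated on the epoch grid; ``span >= 1``
    degenerates to the unweighted global quadratic least-squares fit.
    Returns (fitted curve, pointwise s.e.m. of the raw epoch values).
    """
    if matrix.n_epochs < 2:
        raise ValueError("need at least 2 epochs to smooth")
    rel = matrix.rel_time
    vals = matrix.values
    finite = ~np.isnan(vals)
    tt = np.broadcast_to(rel, vals.shape)[finite]
    yy = vals[finite]
    order = np.argsort(tt, kind="stable")
    tt, yy = tt[order], yy[order]
    t_range = rel[-1] - rel[0]
    halfwidth = 0.5 * span * t_range
    if halfwidth <= (rel[1] - rel[0]):
        raise ValueError("span too small for local quadratic fits")

    fitted = np.empty(rel.size)
    for j, t0 in enumerate(rel):
        if span >= 1.0:
            w = np.ones(tt.size)
            sel = slice(None)
            ts, ys = tt, yy
        else:
            lo, hi = np.searchsorted(tt, (t0 - halfwidth, t0 + halfwidth + 1e-12))
            ts, ys = tt[lo:hi], yy[lo:hi]
            if ts.size < 3:
                raise ValueError("span too small for local quadratic fits")
            u = np.abs(ts - t0) / halfwidth
            w = np.clip(1.0 - u**3, 0.0, None) ** 3
            if not np.any(w > 0):
                w = np.ones(ts.size)
        X = np.column_stack([np.ones(ts.size), ts - t0, (ts - t0) ** 2])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], ys * sw, rcond=None)
        fitted[j] = beta[0]

    n_per_t = finite.sum(axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sem = sd / np.sqrt(np.maximum(n_per_t, 1))
    return fitted, sem
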