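"""Seeded synthetic recording sessions with known ground truth.

The study's raw in-vivo recordings are not deposited, so every downstream
stage is validated against sessions generated here: zone-structured behavior
(semi-Markov occupancy with exponential dwell times), single-cell calcium
traces (Poisson transient trains convolved with an exponential decay kernel,
zone-modulated event rates), dual-channel photometry (double-exponential
bleaching, shared motion artifacts, packet-loss spikes) and cohort-level
anxiety metrics driven by a shared latent trait.

Planted zone effects are requested in s.d. units of the cell's null trace
and converted to a multiplicative event-rate factor using the shot-noise
mean/variance of the exponential-kernel train (Campbell's theorem), so the
trace stays nonnegative while the achieved effect is known exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .session_io import CellTraceSet, EventList, ZoneOccupancy, align_to_trace_clock

logger = logging.getLogger(__name__)

__all__ = [
    "ZoneSpec",
    "CellSpec",
    "PhotometrySpec",
    "SimConfig",
    "GroundTruth",
    "simulate_behavior",
    "simulate_traces",
    "simulate_photometry",
    "simulate_cohort",
    "kernel_sums",
]


@dataclass(frozen=True)
class ZoneSpec:
    name: str
    mean_dwell_s: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_dwell_s <= 0:
            raise ValueError(f"zone {self.name!r}: mean dwell must be > 0")
        if self.weight <= 0:
            raise ValueError(f"zone {self.name!r}: weight must be > 0")


@dataclass(frozen=True)
class CellSpec:
    """One simulated cell: baseline transient rate plus per-zone effects.

    zone_effects maps zone name to a signed effect size in s.d. units of the
    cell's null (baseline-rate) trace; 0 / absent means unmodulated.
    """

    baseline_rate: float  # events / s
    zone_effects: dict[str, float] = field(default_factory=dict)
    decay_tau: float = 1.0  # s

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")
        for z, e in self.zone_effects.items():
            if not math.isfinite(e):
                raise ValueError(f"effect for zone {z!r} must be finite")


@dataclass(frozen=True)
class PhotometrySpec:
    """Dual-channel photometry generator parameters.

    Bleach curves are a1*exp(-b1 t) + a2*exp(-b2 t) per channel; a shared
    motion series enters the primary channel scaled by alpha and the
    isobestic channel scaled by beta; packet-loss samples are replaced by
    spikes of 10x the running IQR so the 4xIQR fence is guaranteed to see
    them.
    """

    bleach_primary: tuple[float, float, float, float] = (5.0, 0.01, 2.0, 0.0005)
    bleach_isobestic: tuple[float, float, float, float] = (4.0, 0.008, 1.5, 0.0004)
    motion_amplitude: float = 0.0
    motion_rate: float = 0.5  # artifacts / s
    alpha: float = 1.0
    beta: float = 1.0
    packet_loss_rate: float = 0.0  # per sample
    noise_sd: float = 0.01
    signal_rate: float = 0.0  # neural transients / s on the primary channel
    signal_amplitude: float = 0.0
    signal_tau: float = 1.0

    def __post_init__(self) -> None:
        for p in (*self.bleach_primary, *self.bleach_isobestic):
            if not math.isfinite(p) or p < 0:
                raise ValueError("bleach parameters must be finite and >= 0")
        if not (0.0 <= self.packet_loss_rate < 1.0):
            raise ValueError("packet_loss_rate must lie in [0, 1)")
        if self.noise_sd < 0 or self.motion_amplitude < 0:
            raise ValueError("noise and motion amplitudes must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    session_duration: float  # s
    zones: tuple[ZoneSpec, ...]
    n_cells: int = 0
    cell_specs: tuple[CellSpec, ...] = ()
    trace_rate: float = 10.0
    track_rate: float = 30.0
    transit_s: float = 1.0  # mean unassigned gap while crossing between zones
    noise_sd: float = 0.5  # white noise on each calcium trace (transient amp = 1)
    photometry: PhotometrySpec = PhotometrySpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_duration <= 0:
            raise ValueError("session_duration must be > 0")
        if self.trace_rate <= 0 or self.track_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.transit_s < 0:
            raise ValueError("transit_s must be >= 0")
        if len(self.zones) == 0:
            raise ValueError("at least one zone must be defined")
        names = [z.name for z in self.zones]
        if len(set(names)) != len(names):
            raise ValueError("zone names must be unique")
        if self.cell_specs and len(self.cell_specs) != self.n_cells:
            raise ValueError("cell_specs length must equal n_cells")

    @property
    def zone_names(self) -> list[str]:
        return [z.name for z in self.zones]


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    cell_labels: list[dict[str, str]] = field(default_factory=list)
    cell_effects: list[dict[str, float]] = field(default_factory=list)
    transient_counts: list[int] = field(default_factory=list)
    artifact_mask: np.ndarray | None = None
    bleach_primary: np.ndarray | None = None
    bleach_isobestic: np.ndarray | None = None
    motion: np.ndarray | None = None
    signal: np.ndarray | None = None
    signal_onsets: np.ndarray | None = None
    latent_trait: np.ndarray | None = None

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "cell_labels": self.cell_labels,
            "cell_effects": self.cell_effects,
            "transient_counts": self.transient_counts,
            "artifact_mask": arr(self.artifact_mask),
            "bleach_primary": arr(self.bleach_primary),
            "bleach_isobestic": arr(self.bleach_isobestic),
            "motion": arr(self.motion),
            "signal": arr(self.signal),
            "signal_onsets": arr(self.signal_onsets),
            "latent_trait": arr(self.latent_trait),
        }


def _rng(seed: int, stream: int) -> np.random.Generator:
    # one master seed; deterministic per-component substreams
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(config: SimConfig) -> tuple[ZoneOccupancy, EventList]:
    """Semi-Markov zone occupancy: exponential dwells, weighted transitions.

    Between visits the animal spends an exponential "transit" interval
    (mean ``config.transit_s``) assigned to no zone, mimicking traversal of
    the arena between zone boundaries.  A single-zone configuration
    degenerates to permanent occupancy with one entry at t = 0.
    """
    rng = _rng(config.seed, 1)
    T = config.session_duration
    zones = list(config.zones)
    names = [z.name for z in zones]
    n_samples = int(round(T * config.track_rate))

    entries: dict[str, list[float]] = {n: [] for n in names}
    exits: dict[str, list[float]] = {n: [] for n in names}
    intervals: list[tuple[int, float, float]] = []  # (zone index, start, end)

    weights = np.array([z.weight for z in zones], dtype=float)
    if len(zones) == 1:
        intervals.append((0, 0.0, T))
        entries[names[0]].append(0.0)
        exits[names[0]].append(T)
    else:
        t = 0.0
        cur = int(rng.choice(len(zones), p=weights / weights.sum()))
        while t < T:
            dwell = rng.exponential(zones[cur].mean_dwell_s)
            end = min(t + dwell, T)
            intervals.append((cur, t, end))
            entries[names[cur]].append(t)
            exits[names[cur]].append(end)
            t = end
            if t >= T:
                break
            if config.transit_s > 0:
                t = min(t + rng.exponential(config.transit_s), T)
                if t >= T:
                    break
            w = weights.copy()
            w[cur] = 0.0
            cur = int(rng.choice(len(zones), p=w / w.sum()))

    ind = np.zeros((len(zones), n_samples), dtype=np.int8)
    times = np.arange(n_samples) / config.track_rate
    for zi, start, end in intervals:
        ind[zi, (times >= start) & (times < end)] = 1

    occ = ZoneOccupancy(zones=names, indicators=ind, rate=config.track_rate)
    events = EventList(
        entries={n: np.array(v) for n, v in entries.items()},
        exits={n: np.array(v) for n, v in exits.items()},
    )
    return occ, events


# ---------------------------------------------------------------------------
# calcium traces


def kernel_sums(trace_rate: float, tau: float) -> tuple[np.ndarray, float, float]:
    """Exponential decay kernel and its first/second power sums.

    Returns (kernel, g1, g2) with g1 = sum(k) and g2 = sum(k**2); for a
    Poisson event train of per-frame rate lam, the convolved trace has mean
    lam*g1 and shot-noise variance lam*g2 (Campbell's theorem).
    """
    n = max(int(round(8.0 * tau * trace_rate)), 1)
    k = np.exp(-np.arange(n + 1) / (tau * trace_rate))
    return k, float(k.sum()), float((k**2).sum())


def _effect_to_rate(
    baseline_rate: float, effect_sd: float, trace_rate: float, tau: float, noise_sd: float
) -> tuple[float, float]:
    """Convert a requested effect (s.d. units of the null trace) to an
    in-zone event rate; returns (zone_rate_per_s, achieved_effect_sd)."""
    _, g1, g2 = kernel_sums(trace_rate, tau)
    lam0 = baseline_rate / trace_rate  # events per frame
    sd_null = math.sqrt(lam0 * g2 + noise_sd**2)
    if sd_null == 0.0:
        return baseline_rate, 0.0
    lam_zone = lam0 + effect_sd * sd_null / g1
    if lam_zone < 0:
        logger.warning(
            "zone effect %.3g s.d. drives event rate negative; clipped to 0",
            effect_sd,
        )
        lam_zone = 0.0
    achieved = (lam_zone - lam0) * g1 / sd_null
    return lam_zone * trace_rate, achieved


def simulate_traces(
    occupancy: ZoneOccupancy, config: SimConfig
) -> tuple[CellTraceSet, GroundTruth]:
    """Poisson transient trains with zone-modulated rates, exponential decay
    kernel, additive white noise."""
    if not config.cell_specs:
        raise ValueError("config.cell_specs must be provided")
    rng = _rng(config.seed, 2)
    n_frames = int(round(config.session_duration * config.trace_rate))
    frame_occ = align_to_trace_clock(occupancy, config.trace_rate, n_frames)

    gt = GroundTruth()
    values = np.empty((config.n_cells, n_frames))
    zone_of_frame = np.full(n_frames, -1, dtype=int)
    for zi in range(len(frame_occ.zones)):
        zone_of_frame[frame_occ.indicators[zi] == 1] = zi

    for ci, spec in enumerate(config.cell_specs):
        kernel, _, _ = kernel_sums(config.trace_rate, spec.decay_tau)
        lam = np.full(n_frames, spec.baseline_rate / config.trace_rate)
        labels: dict[str, str] = {}
        effects: dict[str, float] = {}
        for zi, zname in enumerate(frame_occ.zones):
            eff = spec.zone_effects.get(zname, 0.0)
            rate_z, achieved = _effect_to_rate(
                spec.baseline_rate, eff, config.trace_rate, spec.decay_tau,
                config.noise_sd,
            )
            if eff != 0.0:
                lam[zone_of_frame == zi] = rate_z / config.trace_rate
            labels[zname] = (
                "null" if achieved == 0.0 else ("excited" if achieved > 0 else "inhibited")
            )
            effects[zname] = achieved
        counts = rng.poisson(lam)
        trace = np.convolve(counts.astype(float), kernel)[:n_frames]
        if config.noise_sd > 0:
            trace = trace + rng.normal(0.0, config.noise_sd, n_frames)
        values[ci] = trace
        gt.cell_labels.append(labels)
        gt.cell_effects.append(effects)
        gt.transient_counts.append(int(counts.sum()))

    traces = CellTraceSet(
        values=values,
        rate=config.trace_rate,
        cell_ids=[f"cell{ci:04d}" for ci in range(config.n_cells)],
        session_id="synthetic",
    )
    return traces, gt


# ---------------------------------------------------------------------------
# photometry


def _running_iqr(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running IQR with truncated edge windows."""
    n = x.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        q1, q3 = np.percentile(x[lo:hi], (25, 75))
        out[i] = q3 - q1
    return out


def simulate_photometry(
    occupancy: ZoneOccupancy, config: SimConfig
) -> tuple["PhotometrySession", GroundTruth]:
    """Two-channel photometry: bleach + signal + shared motion + noise,
    with packet-loss spikes and all planted components returned."""
    from .photometry import PhotometrySession  # local import avoids a cycle

    spec = config.photometry
    rng = _rng(config.seed, 3)
    rate = config.track_rate
    n = int(round(config.session_duration * rate))
    t = np.arange(n) / rate

    a1, b1, a2, b2 = spec.bleach_primary
    bleach_p = a1 * np.exp(-b1 * t) + a2 * np.exp(-b2 * t)
    a1i, b1i, a2i, b2i = spec.bleach_isobestic
    bleach_i = a1i * np.exp(-b1i * t) + a2i * np.exp(-b2i * t)

    # shared motion: random-sign decayed bumps at motion_rate events/s
    motion = np.zeros(n)
    if spec.motion_amplitude > 0 and spec.motion_rate > 0:
        n_events = rng.poisson(spec.motion_rate * config.session_duration)
        onsets = np.sort(rng.integers(0, n, size=n_events))
        bump = np.exp(-np.arange(int(0.5 * rate) + 1) / (0.1 * rate))
        impulses = np.zeros(n)
        for o in onsets:
            impulses[o] += rng.choice((-1.0, 1.0)) * spec.motion_amplitude
        motion = np.convolve(impulses, bump)[:n]

    # neural transients on the primary channel only
    signal = np.zeros(n)
    onsets_s = np.empty(0)
    if spec.signal_rate > 0 and spec.signal_amplitude > 0:
        counts = rng.poisson(spec.signal_rate / rate, size=n)
        kernel = spec.signal_amplitude * np.exp(
            -np.arange(int(8 * spec.signal_tau * rate) + 1) / (spec.signal_tau * rate)
        )
        signal = np.convolve(counts.astype(float), kernel)[:n]
        onsets_s = np.flatnonzero(counts) / rate

    noise_p = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
    noise_i = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)

    primary = bleach_p + signal + spec.alpha * motion + noise_p
    isobestic = bleach_i + spec.beta * motion + noise_i

    mask = np.zeros(n, dtype=bool)
    if spec.packet_loss_rate > 0:
        mask = rng.random(n) < spec.packet_loss_rate
        if mask.any():
            iqr = _running_iqr(primary, int(20 * rate))
            primary = primary.copy()
            primary[mask] = primary[mask] + 10.0 * np.maximum(iqr[mask], 1e-6)
            isobestic = isobestic.copy()
            isobestic[mask] = isobestic[mask] + 10.0 * np.maximum(iqr[mask], 1e-6)

    session = PhotometrySession(primary=primary, isobestic=isobestic, rate=rate)
    gt = GroundTruth(
        artifact_mask=mask,
        bleach_primary=bleach_p,
        bleach_isobestic=bleach_i,
        motion=motion,
        signal=signal,
        signal_onsets=onsets_s,
    )
    return session, gt


# ---------------------------------------------------------------------------
# cohort metrics


def simulate_cohort(n_animals: int, trait_effect: float, seed: int = 0):
    """Per-animal anxiety-test metrics driven by a shared latent trait.

    Higher latent trait means a more anxious animal: less time in the EPM
    open arms, less time in the OF center, longer latency to eat in the
    NSFT.  trait_effect scales the trait loading relative to unit
    test-specific noise (0 = independent metrics).

    Returns (DataFrame with columns animal_id, epm_open_s, of_center_s,
    nsft_latency_s; GroundTruth carrying the latent trait).
    """
    import pandas as pd

    if n_animals < 2:
        raise ValueError("need at least 2 animals (z-score undefined otherwise)")
    rng = _rng(seed, 4)
    trait = rng.normal(0.0, 1.0, n_animals)
    denom = math.sqrt(trait_effect**2 + 1.0)

    def standardized(sign: float) -> np.ndarray:
        eps = rng.normal(0.0, 1.0, n_animals)
        return (sign * trait_effect * trait + eps) / denom

    # typical scales: 300-s EPM, 600-s OF, 600-s NSFT cutoff
    epm = np.clip(90.0 + 30.0 * standardized(-1.0), 0.0, 300.0)
    of = np.clip(60.0 + 20.0 * standardized(-1.0), 0.0, 600.0)
    nsft = np.clip(300.0 + 120.0 * standardized(+1.0), 1.0, 600.0)

    table = pd.DataFrame(
        {
            "animal_id": [f"m{i:03d}" for i in range(n_animals)],
            "epm_open_s": epm,
            "of_center_s": of,
            "nsft_latency_s": nsft,
        }
    )
    return table, GroundTruth(latent_trait=trait)
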