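"""Fiber-photometry correction chain.

A dual-channel recording (465-nm calcium-dependent primary, 405-nm
isobestic reference, 30 Hz) is corrected in a fixed order: startup trim,
packet-loss artifact interpolation (4x IQR fence in a 20-s sliding window),
1-s moving-average smoothing, per-channel double-exponential bleaching
baseline fit and subtraction, motion correction by regressing the isobestic
channel onto the primary and subtracting the fit, dF/F division by the
primary channel's fitted baseline, and a final whole-session z-score.
Each stage is exposed on its own and composed by :func:`preprocess`, which
retains every intermediate for inspection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .session_io import provenance_record

__all__ = [
    "PhotometrySession",
    "ProcessedPhotometry",
    "trim_startup",
    "interpolate_artifacts",
    "moving_average",
    "fit_double_exponential",
    "double_exponential",
    "correct_motion",
    "compute_dff",
    "preprocess",
]


@dataclass
class PhotometrySession:
    primary: np.ndarray
    isobestic: np.ndarray
    rate: float = 30.0
    t0: float = 0.0
    stage_outputs: dict = field(default_factory=dict)
    artifact_mask: np.ndarray | None = None
    baseline_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.primary = np.asarray(self.primary, dtype=float)
        self.isobestic = np.asarray(self.isobestic, dtype=float)
        if self.primary.shape != self.isobestic.shape or self.primary.ndim != 1:
            raise ValueError("primary and isobestic must be equal-length 1-D series")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.artifact_mask is not None and len(self.artifact_mask) != len(self.primary):
            raise ValueError("artifact_mask length mismatch")

    @property
    def n_samples(self) -> int:
        return self.primary.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class ProcessedPhotometry:
    dff: np.ndarray
    zscored: np.ndarray
    provenance: list = field(default_factory=list)
    stage_outputs: dict = field(default_factory=dict)
    artifact_mask: np.ndarray | None = None
    baseline_params: dict = field(default_factory=dict)


def trim_startup(session: PhotometrySession, trim_s: float = 5.0) -> PhotometrySession:
    """Drop the first ``trim_s`` seconds (startup transients) from all series."""
    n_trim = int(round(trim_s * session.rate))
    if session.n_samples <= n_trim:
        raise ValueError(
            f"session of {session.duration:.1f}s is not longer than trim {trim_s}s"
        )
    return PhotometrySession(
        primary=session.primary[n_trim:].copy(),
        isobestic=session.isobestic[n_trim:].copy(),
        rate=session.rate,
        t0=session.t0 + trim_s,
        artifact_mask=(
            session.artifact_mask[n_trim:].copy()
            if session.artifact_mask is not None
            else None
        ),
    )


def interpolate_artifacts(
    series: np.ndarray, rate: float, window_s: float = 20.0, k: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag packet-loss spikes with a sliding IQR fence and interpolate them.

    A sample is flagged when it falls outside [Q1 - k*IQR, Q3 + k*IQR] of a
    centered ``window_s`` window (truncated at the edges, stride one
    sample).  Flagged runs are replaced by linear interpolation between the
    nearest unflagged neighbors.  Returns (cleaned series, boolean mask).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    window = int(round(window_s * rate))
    if window < 8:
        raise ValueError("window must span at least 8 samples")
    half = window // 2
    width = 2 * half + 1  # symmetric centered window (odd)

    q1 = np.empty(n)
    q3 = np.empty(n)
    # full interior windows vectorized; truncated edges individually
    if n >= width:
        from numpy.lib.stride_tricks import sliding_window_view

        wv = sliding_window_view(x, width)
        qs = np.percentile(wv, (25, 75), axis=1)
        centers = np.arange(wv.shape[0]) + half
        q1[centers] = qs[0]
        q3[centers] = qs[1]
        edge_idx = [i for i in range(n) if i < half or i > int(centers[-1])]
    else:
        edge_idx = list(range(n))
    for i in edge_idx:
        lo, hi = max(0, i - half), min(n, i + half + 1)
        q1[i], q3[i] = np.percentile(x[lo:hi], (25, 75))

    iqr = q3 - q1
    mask = (x < q1 - k * iqr) | (x > q3 + k * iqr)
    if mask.sum() > 0.5 * n:
        raise ValueError(
            f"{mask.sum()} of {n} samples flagged as artifacts; signal unusable"
        )
    cleaned = x.copy()
    if mask.any():
        good = ~mask
        if not good.any():
            raise ValueError("all samples flagged")
        idx = np.arange(n)
        cleaned[mask] = np.interp(idx[mask], idx[good], x[good])
    return cleaned, mask


def moving_average(series: np.ndarray, rate: float, window_s: float = 1.0) -> np.ndarray:
    """Centered moving mean with truncated windows at the edges."""
    x = np.asarray(series, dtype=float)
    window = max(int(round(window_s * rate)), 1)
    half = window // 2
    # cumulative-sum formulation of the truncated centered mean
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def double_exponential(t: np.ndarray, a1: float, b1: float, a2: float, b2: float) -> np.ndarray:
    return a1 * np.exp(-b1 * t) + a2 * np.exp(-b2 * t)


def fit_double_exponential(
    series: np.ndarray, rate: float
) -> tuple[tuple[float, float, float, float], np.ndarray]:
    """Nonlinear least-squares bleaching baseline a1*e^(-b1 t) + a2*e^(-b2 t).

    All parameters constrained nonnegative; a near-zero decay term plays the
    role of an additive constant.  Deterministic initialization (fast + slow
    decay split of the series mean) with one jittered restart; the better
    residual wins.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 samples to fit a baseline")
    t = np.arange(x.size) / rate
    T = t[-1] if t[-1] > 0 else 1.0
    mean = float(np.mean(x))
    inits = [
        (max(mean, 1e-12) / 2, 5.0 / T, max(mean, 1e-12) / 2, 0.5 / T),
        (max(mean, 1e-12) * 0.75, 10.0 / T, max(mean, 1e-12) * 0.25, 0.05 / T),
    ]
    best = None
    best_res = math.inf
    last_err: Exception | None = None
    for p0 in inits:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    double_exponential,
                    t,
                    x,
                    p0=p0,
                    bounds=(0.0, np.inf),
                    maxfev=20000,
                )
            res = float(np.sum((double_exponential(t, *popt) - x) ** 2))
            if res < best_res:
                best_res, best = res, tuple(float(p) for p in popt)
        except RuntimeError as e:
            last_err = e
    if best is None:
        raise RuntimeError(
            f"double-exponential fit failed to converge: {last_err}"
        )
    return best, double_exponential(t, *best)


def correct_motion(
    primary: np.ndarray, isobestic: np.ndarray
) -> tuple[np.ndarray, tuple[float, float]]:
    """Subtract the OLS fit of the isobestic channel from the primary.

    Both inputs are baseline-subtracted.  Returns (corrected, (slope,
    intercept)).  A constant isobestic channel carries no motion information,
    so the slope is set to 0 with a warning.
    """
    p = np.asarray(primary, dtype=float)
    i = np.asarray(isobestic, dtype=float)
    if p.shape != i.shape:
        raise ValueError("channels must have equal length")
    var = float(np.var(i))
    if var == 0.0:
        warnings.warn("isobestic channel is constant; motion slope set to 0")
        slope = 0.0
    else:
        slope = float(np.cov(p, i, ddof=0)[0, 1] / var)
    intercept = float(np.mean(p) - slope * np.mean(i))
    return p - (slope * i + intercept), (slope, intercept)


def compute_dff(corrected: np.ndarray, baseline_curve: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """dF/F: corrected signal divided by the fitted bleaching baseline."""
    c = np.asarray(corrected, dtype=float)
    b = np.asarray(baseline_curve, dtype=float)
    if c.shape != b.shape:
        raise ValueError("corrected and baseline must have equal length")
    if np.any(b <= eps):
        raise ValueError("baseline curve not strictly positive; division unsafe")
    return c / b


def preprocess(
    session: PhotometrySession,
    trim_s: float = 5.0,
    artifact_window_s: float = 20.0,
    artifact_k: float = 4.0,
    smooth_window_s: float = 1.0,
) -> ProcessedPhotometry:
    """Full correction chain, all intermediates kept in ``stage_outputs``.

    Order: trim -> artifact interpolation (both channels) -> moving-average
    smoothing (both) -> per-channel double-exponential baseline fit and
    subtraction -> motion correction (fitted isobestic subtracted from
    primary) -> dF/F against the primary baseline -> whole-session z-score
    (sample s.d.).
    """
    prov: list = []
    stages: dict = {}
    rate = session.rate

    s = trim_startup(session, trim_s)
    stages["trimmed_primary"] = s.primary.copy()
    stages["trimmed_isobestic"] = s.isobestic.copy()
    prov.append(provenance_record("trim_startup", {"trim_s": trim_s}))

    p_clean, p_mask = interpolate_artifacts(s.primary, rate, artifact_window_s, artifact_k)
    i_clean, i_mask = interpolate_artifacts(s.isobestic, rate, artifact_window_s, artifact_k)
    mask = p_mask | i_mask
    stages["deartifacted_primary"] = p_clean
    stages["deartifacted_isobestic"] = i_clean
    prov.append(
        provenance_record(
            "interpolate_artifacts",
            {"window_s": artifact_window_s, "k": artifact_k,
             "flagged_primary": int(p_mask.sum()), "flagged_isobestic": int(i_mask.sum())},
        )
    )

    p_smooth = moving_average(p_clean, rate, smooth_window_s)
    i_smooth = moving_average(i_clean, rate, smooth_window_s)
    stages["smoothed_primary"] = p_smooth
    stages["smoothed_isobestic"] = i_smooth
    prov.append(provenance_record("moving_average", {"window_s": smooth_window_s}))

    params_p, base_p = fit_double_exponential(p_smooth, rate)
    params_i, base_i = fit_double_exponential(i_smooth, rate)
    p_detrended = p_smooth - base_p
    i_detrended = i_smooth - base_i
    stages["baseline_primary"] = base_p
    stages["baseline_isobestic"] = base_i
    stages["detrended_primary"] = p_detrended
    stages["detrended_isobestic"] = i_detrended
    prov.append(
        provenance_record(
            "fit_double_exponential",
            {"primary_params": list(params_p), "isobestic_params": list(params_i)},
        )
    )

    corrected, (slope, intercept) = correct_motion(p_detrended, i_detrended)
    stages["motion_corrected"] = corrected
    prov.append(
        provenance_record("correct_motion", {"slope": slope, "intercept": intercept})
    )

    dff = compute_dff(corrected, base_p)
    stages["dff"] = dff
    prov.append(provenance_record("compute_dff", {}))

    sd = float(np.std(dff, ddof=1))
    if sd == 0.0:
        raise ValueError("dF/F is constant; cannot z-score")
    zscored = (dff - float(np.mean(dff))) / sd
    stages["zscored"] = zscored
    prov.append(provenance_record("zscore", {"ddof": 1}))

    return ProcessedPhotometry(
        dff=dff,
        zscored=zscored,
        provenance=prov,
        stage_outputs=stages,
        artifact_mask=mask,
        baseline_params={"primary": params_p, "isobestic": params_i},
    )
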