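"""Straightforward loop-based reference implementations.

Deliberately unvectorized, independently coded versions of the photometry
stages, binning and window means.  They exist purely to validate the fast
implementations (stage-equivalence checks in the test suite and the
reproduction script); nothing in the pipeline calls them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "naive_moving_average",
    "naive_interpolate_artifacts",
    "naive_correct_motion",
    "naive_dff",
    "naive_zscore",
    "naive_bin_signal",
    "naive_window_mean",
]


def naive_moving_average(series, rate, window_s=1.0):
    x = list(map(float, series))
    n = len(x)
    window = max(int(round(window_s * rate)), 1)
    half = window // 2
    out = []
    for i in range(n):
        lo = i - half if i - half > 0 else 0
        hi = i + half + 1 if i + half + 1 < n else n
        total = 0.0
        for j in range(lo, hi):
            total += x[j]
        out.append(total / (hi - lo))
    return np.array(out)


def _percentile(sorted_vals, q):
    # linear interpolation between closest ranks (numpy default)
    n = len(sorted_vals)
    pos = (q / 100.0) * (n - 1)
    lo = int(pos)
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def naive_interpolate_artifacts(series, rate, window_s=20.0, k=4.0):
    x = list(map(float, series))
    n = len(x)
    window = int(round(window_s * rate))
    half = window // 2
    mask = [False] * n
    for i in range(n):
        lo = i - half if i - half > 0 else 0
        hi = i + half + 1 if i + half + 1 < n else n
        vals = sorted(x[lo:hi])
        q1 = _percentile(vals, 25)
        q3 = _percentile(vals, 75)
        iqr = q3 - q1
        if x[i] < q1 - k * iqr or x[i] > q3 + k * iqr:
            mask[i] = True
    cleaned = list(x)
    for i in range(n):
        if not mask[i]:
            continue
        left = i - 1
        while left >= 0 and mask[left]:
            left -= 1
        right = i + 1
        while right < n and mask[right]:
            right += 1
        if left < 0 and right >= n:
            continue
        if left < 0:
            cleaned[i] = x[right]
        elif right >= n:
            cleaned[i] = x[left]
        else:
            frac = (i - left) / (right - left)
            cleaned[i] = x[left] + frac * (x[right] - x[left])
    return np.array(cleaned), np.array(mask)


def naive_correct_motion(primary, isobestic):
    p = list(map(float, primary))
    q = list(map(float, isobestic))
    n = len(p)
    mp = sum(p) / n
    mq = sum(q) / n
    sxy = 0.0
    sxx = 0.0
    for a, b in zip(p, q):
        sxy += (a - mp) * (b - mq)
        sxx += (b - mq) ** 2
    slope = 0.0 if sxx == 0 else sxy / sxx
    intercept = mp - slope * mq
    return np.array([a - (slope * b + intercept) for a, b in zip(p, q)])


def naive_dff(corrected, baseline):
    return np.array([c / b for c, b in zip(corrected, baseline)])


def naive_zscore(series):
    x = list(map(float, series))
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / (n - 1)
    sd = var**0.5
    return np.array([(v - mean) / sd for v in x])


def naive_bin_signal(trace, rate, bin_s=1.0):
    x = list(map(float, trace))
    per_bin = int(round(bin_s * rate))
    out = []
    i = 0
    while i + per_bin <= len(x):
        out.append(sum(x[i : i + per_bin]) / per_bin)
        i += per_bin
    return np.array(out)


def naive_window_mean(values, rel_time, start_s, end_s):
    """Per-epoch mean over samples with start <= t < end; NaN rows skipped."""
    per_epoch = []
    for row in values:
        acc = []
        for v, t in zip(row, rel_time):
            if start_s <= t < end_s:
                acc.append(float(v))
        if any(np.isnan(a) for a in acc):
            per_epoch.append(float("nan"))
        else:
            per_epoch.append(sum(acc) / len(acc))
    return np.array(per_epoch)
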