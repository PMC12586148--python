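"""Cross-test anxiety scoring and low/high categorization.

Each behavioral test yields one raw metric per animal (EPM: time in open
arms; OF: time in arena center; NSFT: latency to eat).  Metrics are
cohort-z-scored (sample s.d.), the EPM and OF scores are sign-flipped so
that a higher score always means a more anxious animal, the overall score
averages the available per-test scores, and animals are split at the cohort
median (ties assigned "low").
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import statcore

logger = logging.getLogger(__name__)

__all__ = [
    "SIGN_FLIPPED_TESTS",
    "test_score",
    "overall_score",
    "split_by_median",
    "score_table",
    "relate",
]

# tests whose raw metric decreases with anxiety (more open-arm / center time
# = less anxious) and whose z-scores are therefore multiplied by -1
SIGN_FLIPPED_TESTS = frozenset({"epm", "of"})

_METRIC_COLUMNS = {
    "epm": "epm_open_s",
    "of": "of_center_s",
    "nsft": "nsft_latency_s",
}


def test_score(raw_values, test_id: str) -> np.ndarray:
    """Cohort z-score of one test's raw metric, anxiety-oriented.

    z = (x - mean) / sample s.d., then multiplied by -1 for EPM and OF so
    that higher always means more anxious.
    """
    x = np.asarray(raw_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 animals")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"test {test_id!r}: constant values, s.d. = 0")
    z = (x - x.mean()) / sd
    if test_id.lower() in SIGN_FLIPPED_TESTS:
        z = -z
    return z


def overall_score(per_test_scores: pd.DataFrame) -> np.ndarray:
    """Mean of available per-test scores per animal (row).

    Missing tests (NaN) are excluded from the mean with a logged count; an
    animal with no tests at all is an error.
    """
    scores = per_test_scores.to_numpy(dtype=float)
    n_available = (~np.isnan(scores)).sum(axis=1)
    if np.any(n_available == 0):
        bad = np.flatnonzero(n_available == 0)
        raise ValueError(f"animals with no test scores at rows {bad.tolist()}")
    n_missing = int(np.isnan(scores).sum())
    if n_missing:
        logger.info("overall_score: %d missing test scores excluded", n_missing)
    return np.nanmean(scores, axis=1)


def split_by_median(scores) -> np.ndarray:
    """Median split: score > median -> 'high', otherwise 'low'.

    Ties at the median are assigned 'low' (deterministic, conservative).
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 animals")
    med = float(np.median(x))
    return np.where(x > med, "high", "low")


def score_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Full anxiety table from raw metrics.

    ``metrics`` needs an ``animal_id`` column plus any of ``epm_open_s``,
    ``of_center_s``, ``nsft_latency_s``.  Adds per-test z-scores
    (``*_score``), the overall score and the low/high category.
    """
    out = metrics.copy()
    score_cols = []
    for test, col in _METRIC_COLUMNS.items():
        if col in out.columns:
            out[f"{test}_score"] = test_score(out[col].to_numpy(), test)
            score_cols.append(f"{test}_score")
    if not score_cols:
        raise ValueError("no recognized metric columns present")
    out["anxiety_score"] = overall_score(out[score_cols])
    out["category"] = split_by_median(out["anxiety_score"].to_numpy())
    return out


def relate(scores, neural_measure) -> dict:
    """Pearson correlation of anxiety scores with a per-animal neural
    measure, with the least-squares line for plotting."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(neural_measure, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {
        "r": float(r),
        "p_value": float(p),
        "n": int(x.size),
        "slope": float(slope),
        "intercept": float(intercept),
    }


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> statcore.TestResult:
    """Fisher-z comparison of two independent correlations (delegated)."""
    return statcore.fisher_z_compare(r1, n1, r2, n2)
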