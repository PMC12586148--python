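"""Responsive-cell classification by per-cell linear models.

Each cell's session-z-scored, 1-s-binned activity is regressed on binary
zone-occupancy predictors (plus an intercept).  A cell is "excited" by a
zone when that zone's coefficient is significantly positive after
Benjamini-Hochberg correction (within each predictor, across the cells of a
session), "inhibited" when significantly negative, "nonresponsive"
otherwise.  An optional effect-size gate (used for recordings in small
enclosures where the animal is never far from any zone) additionally
requires |coefficient| to exceed a threshold in s.d. units — traces are
z-scored, so coefficients are already on that scale.  Proportions of
responsive cells are compared with a two-sample z test (within condition)
or a Pearson chi-squared test (across conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from . import statcore
from .perievent import bin_signal
from .session_io import ZoneOccupancy

__all__ = [
    "build_design",
    "classify_cells",
    "classify_stim_modulation",
    "proportion_report",
    "proportion_across_conditions",
]


def build_design(
    occupancy: ZoneOccupancy, bin_s: float = 1.0, threshold: float = 0.5
) -> pd.DataFrame:
    """Binary zone predictors on the binned clock.

    Each bin's value is the fraction of the bin spent in the zone,
    binarized at ``threshold`` (strictly greater).  No intercept column —
    the fitting routine adds one.
    """
    per_bin = bin_s * occupancy.rate
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ValueError("bin_s must be a multiple of the sample period")
    cols = {}
    for zi, zone in enumerate(occupancy.zones):
        frac = bin_signal(occupancy.indicators[zi].astype(float), occupancy.rate, bin_s)
        cols[zone] = (frac > threshold).astype(float)
    design = pd.DataFrame(cols)
    for zone in design.columns:
        if design[zone].sum() == 0:
            warnings.warn(f"zone {zone!r} never occupied at the bin level")
    return design


def _check_rank(design: pd.DataFrame) -> None:
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved: those whose removal restores full rank
        bad = []
        for col in design.columns:
            Xr = np.column_stack(
                [np.ones(len(design)), design.drop(columns=[col]).to_numpy(dtype=float)]
            )
            if np.linalg.matrix_rank(Xr) == Xr.shape[1]:
                bad.append(col)
        raise ValueError(
            "design matrix is rank deficient (collinear with intercept); "
            f"involved columns: {bad or list(design.columns)}"
        )


def classify_cells(
    binned_traces: np.ndarray,
    design: pd.DataFrame,
    cell_ids: list[str] | None = None,
    alpha: float = 0.05,
    effect_gate: float = 0.0,
) -> pd.DataFrame:
    """Per-cell OLS on zone predictors; BH-adjusted labels per predictor.

    ``binned_traces`` is cells x bins, already z-scored per cell across the
    session.  Returns a tidy ResponseTable with one row per (cell,
    predictor): coefficient, raw p, BH q (family = this predictor across all
    cells), effect-gate flag and label.
    """
    Y = np.atleast_2d(np.asarray(binned_traces, dtype=float))
    if Y.shape[1] != len(design):
        raise ValueError(
            f"trace bins ({Y.shape[1]}) must match design rows ({len(design)})"
        )
    _check_rank(design)
    if cell_ids is None:
        cell_ids = [f"cell{i:04d}" for i in range(Y.shape[0])]
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    predictors = list(design.columns)

    rows = []
    for ci in range(Y.shape[0]):
        fit = sm.OLS(Y[ci], X).fit()
        for pi, pred in enumerate(predictors, start=1):
            rows.append(
                {
                    "cell_id": cell_ids[ci],
                    "predictor": pred,
                    "coefficient": float(fit.params[pi]),
                    "p_raw": float(fit.pvalues[pi]),
                }
            )
    table = pd.DataFrame(rows)

    table["q_adj"] = np.nan
    for pred in predictors:
        sel = table["predictor"] == pred
        table.loc[sel, "q_adj"] = statcore.bh_adjust(table.loc[sel, "p_raw"].to_numpy())

    gate_ok = (
        np.abs(table["coefficient"]) > effect_gate
        if effect_gate > 0
        else pd.Series(True, index=table.index)
    )
    table["effect_gate_passed"] = gate_ok
    significant = (table["q_adj"] < alpha) & gate_ok
    table["label"] = "nonresponsive"
    table.loc[significant & (table["coefficient"] > 0), "label"] = "excited"
    table.loc[significant & (table["coefficient"] < 0), "label"] = "inhibited"
    return table


def classify_stim_modulation(
    binned_traces: np.ndarray,
    stim_phase: np.ndarray,
    cell_ids: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify cells excited/inhibited by an alternating stimulation phase.

    ``stim_phase`` is the binary ON indicator on the binned clock (e.g. a
    5-min OFF/ON cycle).  Same linear-model machinery with the single ON
    predictor.
    """
    phase = np.asarray(stim_phase, dtype=float)
    if np.all(phase == phase[0]):
        raise ValueError("stimulation phase is constant; no contrast to fit")
    design = pd.DataFrame({"stim_on": phase})
    return classify_cells(binned_traces, design, cell_ids=cell_ids, alpha=alpha)


@dataclass(frozen=True)
class ProportionReport:
    counts: tuple[int, int]
    totals: tuple[int, int]
    proportions: tuple[float, float]
    z: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "counts": list(self.counts),
            "totals": list(self.totals),
            "proportions": list(self.proportions),
            "z": self.z,
            "p_value": self.p_value,
        }


def proportion_report(
    table: pd.DataFrame,
    predictor_a: str,
    predictor_b: str,
    label: str = "excited",
) -> ProportionReport:
    """Compare the proportion of ``label`` cells between two predictors
    over the same cell population (two-sample z test, pooled variance)."""
    for pred in (predictor_a, predictor_b):
        if not (table["predictor"] == pred).any():
            raise ValueError(f"predictor {pred!r} not present in the table")
    sub_a = table[table["predictor"] == predictor_a]
    sub_b = table[table["predictor"] == predictor_b]
    n1, n2 = len(sub_a), len(sub_b)
    if n1 == 0 or n2 == 0:
        raise ValueError("no cells for one of the predictors")
    k1 = int((sub_a["label"] == label).sum())
    k2 = int((sub_b["label"] == label).sum())
    res = statcore.two_proportion_z(k1, n1, k2, n2, pooled=True)
    return ProportionReport(
        counts=(k1, k2),
        totals=(n1, n2),
        proportions=(k1 / n1, k2 / n2),
        z=res.statistic,
        p_value=res.p_value,
    )


def proportion_across_conditions(*counts: tuple[int, int]) -> statcore.TestResult:
    """Pearson chi-squared on a responsive/nonresponsive x condition table.

    Each argument is (n_responsive, n_nonresponsive) for one condition; no
    continuity correction, so on a 2x2 table the statistic equals z**2 from
    the pooled two-proportion test.
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 conditions")
    obs = np.asarray(counts, dtype=float)
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    if np.any(expected < 1):
        warnings.warn("chi-squared expected count below 1; test unreliable")
    return statcore.TestResult(
        statistic=float(chi2),
        p_value=float(min(p, 1.0)),
        sidedness="two-sided",
        n=tuple(int(r.sum()) for r in obs),
        method="Pearson chi-squared",
        extra={"dof": int(dof)},
    )
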