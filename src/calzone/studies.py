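"""Seeded validation studies over synthetic sessions.

Each function simulates sessions under the package's reference study
conditions (see docs/methods.md), runs the relevant pipeline stage and
returns the measured quantities.  The test suite asserts on these numbers
and ``scripts/acceptance.py`` re-computes and reports them; keeping the
studies here guarantees both always measure the same thing.

Reference conditions: ABA-like arena with food / running-wheel / neutral
zones (mean dwells 10, 10, 15 s; 2-s mean transit), cells with baseline
transient rate 0.5 events/s, decay tau 1 s, white-noise s.d. 0.5 (unit
transient amplitude), 15-min sessions at 10 Hz traces / 30 Hz tracking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import anxiety, cellclass, decoding, naive, perievent, photometry, population
from .synthgen import CellSpec, PhotometrySpec, SimConfig, ZoneSpec, simulate_behavior, simulate_photometry, simulate_traces

__all__ = [
    "classification_session",
    "fdr_null_study",
    "label_recovery_study",
    "photometry_equivalence_study",
    "motion_correction_study",
    "decoding_study",
    "anxiety_exactness_study",
    "identity_checks_study",
    "perievent_fidelity_study",
    "pipeline_report",
]

_ZONES = (ZoneSpec("food", 10.0), ZoneSpec("rw", 10.0), ZoneSpec("neutral", 15.0))
_RATE = 0.5  # baseline transients / s
_NOISE = 0.5
_DURATION = 900.0  # 15-min sessions
_TRANSIT = 2.0


def classification_session(
    seed: int, n_cells: int, effects
) -> tuple[np.ndarray, pd.DataFrame, list[dict], "object"]:
    """Simulate one reference session and prepare it for classification.

    ``effects`` maps cell index -> zone-effect dict.  Returns (binned
    z-scored traces, design matrix, ground-truth labels per cell, occupancy).
    """
    specs = tuple(CellSpec(_RATE, effects(i)) for i in range(n_cells))
    cfg = SimConfig(
        session_duration=_DURATION,
        zones=_ZONES,
        n_cells=n_cells,
        cell_specs=specs,
        transit_s=_TRANSIT,
        noise_sd=_NOISE,
        seed=seed,
    )
    occ, _ = simulate_behavior(cfg)
    traces, gt = simulate_traces(occ, cfg)
    z = traces.zscored()
    binned = np.vstack(
        [perievent.bin_signal(z.values[i], z.rate) for i in range(n_cells)]
    )
    design = cellclass.build_design(occ)
    return binned, design, gt.cell_labels, occ


def fdr_null_study(seed: int, n_cells: int = 300, n_seeds: int = 10) -> dict:
    """Modulated fraction among pure-noise cells (no zone effects), per seed."""
    fractions = []
    for s in range(n_seeds):
        binned, design, _, _ = classification_session(seed + s, n_cells, lambda i: {})
        table = cellclass.classify_cells(binned, design, alpha=0.05)
        modulated = (
            (table["label"] != "nonresponsive").groupby(table["cell_id"]).any()
        )
        fractions.append(float(modulated.mean()))
    return {
        "per_seed": fractions,
        "max_fraction": max(fractions),
        "mean_fraction": float(np.mean(fractions)),
        "n_cells": n_cells,
        "n_seeds": n_seeds,
    }


def label_recovery_study(
    seed: int, n_excited: int = 40, n_inhibited: int = 20, n_null: int = 40
) -> dict:
    """Recovery of planted +0.5 / -0.5 s.d. zone effects in one session."""
    n_cells = n_excited + n_inhibited + n_null

    def effects(i):
        if i < n_excited:
            return {"food": 0.5}
        if i < n_excited + n_inhibited:
            return {"food": -0.5}
        return {}

    binned, design, true_labels, _ = classification_session(seed, n_cells, effects)
    table = cellclass.classify_cells(binned, design, alpha=0.05)
    food = table[table["predictor"] == "food"].set_index("cell_id")
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    pred = food.loc[cell_ids, "label"].to_numpy()
    true = np.array([true_labels[i]["food"] for i in range(n_cells)])

    planted = true != "null"
    detected = pred[planted] != "nonresponsive"
    sensitivity = float((pred[planted] == true[planted]).mean())
    direction_acc = (
        float((pred[planted][detected] == true[planted][detected]).mean())
        if detected.any()
        else 1.0
    )
    null_ids = set(cell_ids[n_excited + n_inhibited :])
    null_rows = table[table["cell_id"].isin(null_ids)]
    fp_rate = float((null_rows["label"] != "nonresponsive").mean())
    return {
        "sensitivity": sensitivity,
        "direction_accuracy": direction_acc,
        "false_positive_rate": fp_rate,
        "n_cells": n_cells,
    }


def photometry_equivalence_study(seed: int, duration: float = 600.0) -> dict:
    """Vectorized photometry stages vs naive-loop references on a synthetic
    10-min trace, plus bleach-curve recovery error."""
    cfg = SimConfig(
        session_duration=duration,
        zones=(ZoneSpec("arena", 30.0),),
        photometry=PhotometrySpec(
            motion_amplitude=0.2,
            motion_rate=0.5,
            packet_loss_rate=0.001,
            noise_sd=0.01,
            signal_rate=0.1,
            signal_amplitude=0.2,
        ),
        seed=seed,
    )
    occ, _ = simulate_behavior(cfg)
    session, gt = simulate_photometry(occ, cfg)
    rate = session.rate
    x = session.primary

    errs = {}
    fast_clean, fast_mask = photometry.interpolate_artifacts(x, rate)
    ref_clean, ref_mask = naive.naive_interpolate_artifacts(x, rate)
    errs["interpolate"] = float(np.max(np.abs(fast_clean - ref_clean)))
    errs["interpolate_mask"] = float(np.max(np.abs(fast_mask.astype(int) - ref_mask.astype(int))))
    sm = photometry.moving_average(fast_clean, rate)
    errs["moving_average"] = float(
        np.max(np.abs(sm - naive.naive_moving_average(fast_clean, rate)))
    )
    params, curve = photometry.fit_double_exponential(sm, rate)
    detr_p = sm - curve
    iso_clean, _ = photometry.interpolate_artifacts(session.isobestic, rate)
    iso_sm = photometry.moving_average(iso_clean, rate)
    _, iso_curve = photometry.fit_double_exponential(iso_sm, rate)
    detr_i = iso_sm - iso_curve
    corrected, _ = photometry.correct_motion(detr_p, detr_i)
    errs["correct_motion"] = float(
        np.max(np.abs(corrected - naive.naive_correct_motion(detr_p, detr_i)))
    )
    dff = photometry.compute_dff(corrected, curve)
    errs["dff"] = float(np.max(np.abs(dff - naive.naive_dff(corrected, curve))))
    z = (dff - dff.mean()) / dff.std(ddof=1)
    errs["zscore"] = float(np.max(np.abs(z - naive.naive_zscore(dff))))

    # bleach recovery on a clean planted curve at noise s.d. 0.01
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * rate)) / rate
    a1, b1, a2, b2 = 5.0, 0.01, 2.0, 0.0005
    clean = a1 * np.exp(-b1 * t) + a2 * np.exp(-b2 * t)
    _, fitted = photometry.fit_double_exponential(
        clean + rng.normal(0.0, 0.01, t.size), rate
    )
    rmse = float(np.sqrt(np.mean((fitted - clean) ** 2)))
    amplitude = float(clean.max() - clean.min())
    return {
        "stage_max_abs_err": max(
            errs[k] for k in ("interpolate", "moving_average", "correct_motion", "dff", "zscore")
        ),
        "per_stage": errs,
        "bleach_rmse": rmse,
        "bleach_rmse_pct_amplitude": 100.0 * rmse / amplitude,
        "n_samples": int(duration * rate),
    }


def motion_correction_study(seed: int, n_seeds: int = 10) -> dict:
    """Shared planted motion artifact before/after isobestic correction."""
    before, after = [], []
    for s in range(n_seeds):
        cfg = SimConfig(
            session_duration=600.0,
            zones=(ZoneSpec("arena", 30.0),),
            photometry=PhotometrySpec(
                motion_amplitude=0.3,
                motion_rate=0.5,
                noise_sd=0.01,
                signal_rate=0.1,
                signal_amplitude=0.1,
            ),
            seed=seed + s,
        )
        occ, _ = simulate_behavior(cfg)
        session, gt = simulate_photometry(occ, cfg)
        proc = photometry.preprocess(session)
        n_trim = int(round(5.0 * session.rate))
        motion = gt.motion[n_trim:]
        raw_detr = session.primary[n_trim:] - gt.bleach_primary[n_trim:]
        before.append(float(np.corrcoef(raw_detr, motion)[0, 1]))
        after.append(
            float(np.corrcoef(proc.stage_outputs["motion_corrected"], motion)[0, 1])
        )
    return {
        "corr_before": before,
        "corr_after": after,
        "min_abs_before": float(np.min(np.abs(before))),
        "max_abs_after": float(np.max(np.abs(after))),
        "n_seeds": n_seeds,
    }


def decoding_study(seed: int, n_cells: int = 200, separation: float = 6.0) -> dict:
    """Decoder calibration: separable planted features and a shuffled null."""
    rng = np.random.default_rng(seed)
    n_a = n_cells // 2
    labels = np.array(["habituation"] * n_a + ["restriction"] * (n_cells - n_a))
    X = rng.normal(0.0, 1.0, (n_cells, 3))
    X[labels == "restriction"] += separation
    report = decoding.train_eval(X, labels, train_frac=0.7, sigma=0.87, cost=1.0, seed=seed)

    shuffled = rng.permutation(labels)
    null_report = decoding.train_eval(
        X, shuffled, train_frac=0.7, sigma=0.87, cost=1.0, seed=seed
    )
    nir = null_report.no_information_rate
    se = float(np.sqrt(nir * (1 - nir) / null_report.n_test))
    return {
        "accuracy": report.accuracy,
        "nir": report.no_information_rate,
        "binomial_p": report.binomial_p,
        "n_test": report.n_test,
        "shuffled_accuracy": null_report.accuracy,
        "shuffled_nir": nir,
        "shuffled_gap_se_units": (
            abs(null_report.accuracy - nir) / se if se > 0 else 0.0
        ),
    }


def anxiety_exactness_study(seed: int, n_animals: int = 16) -> dict:
    """Numerical exactness of the anxiety scoring chain."""
    from .synthgen import simulate_cohort

    metrics, _ = simulate_cohort(n_animals, trait_effect=1.0, seed=seed)
    table = anxiety.score_table(metrics)
    score_cols = ["epm_score", "of_score", "nsft_score"]
    max_mean = max(abs(float(table[c].mean())) for c in score_cols)
    max_sd_err = max(abs(float(table[c].std(ddof=1)) - 1.0) for c in score_cols)
    counts = table["category"].value_counts()
    split_diff = abs(int(counts.get("low", 0)) - int(counts.get("high", 0)))
    # EPM monotonicity on a clean ramp
    ramp = anxiety.test_score(np.arange(1.0, 9.0), "epm")
    monotone = bool(np.all(np.diff(ramp) < 0))
    return {
        "max_score_mean_abs": max_mean,
        "max_score_sd_err": max_sd_err,
        "split_size_diff": split_diff,
        "epm_strictly_decreasing": monotone,
        "n_animals": n_animals,
    }


def identity_checks_study(seed: int) -> dict:
    """Closed-form identities among the statistics and population tools."""
    from itertools import product

    from scipy import stats as sps

    from . import statcore

    rng = np.random.default_rng(seed)
    # z^2 == chi^2 on random 2x2 tables
    max_diff = 0.0
    for _ in range(20):
        n1, n2 = rng.integers(20, 200, 2)
        k1 = int(rng.integers(1, n1))
        k2 = int(rng.integers(1, n2))
        z = statcore.two_proportion_z(k1, int(n1), k2, int(n2)).statistic
        chi2 = cellclass.proportion_across_conditions(
            (k1, int(n1) - k1), (k2, int(n2) - k2)
        ).statistic
        max_diff = max(max_diff, abs(z**2 - chi2))

    # BH hand-worked example
    q = statcore.bh_adjust([0.01, 0.02, 0.03])
    bh_exact = float(np.max(np.abs(q - 0.03)))

    # exact binomial vs enumeration for n <= 20
    binom_err = 0.0
    for n, p0 in product((5, 12, 20), (0.3, 0.5, 0.7)):
        for k in range(n + 1):
            ours = statcore.exact_binomial(k, n, p0, "greater").p_value
            brute = sum(sps.binom.pmf(j, n, p0) for j in range(k, n + 1))
            binom_err = max(binom_err, abs(ours - brute))

    # PCA invariants
    X = rng.normal(size=(60, 5))
    res = population.pca(X)
    frac_sum_err = abs(float(res.variance_fractions.sum()) - 1.0)
    ortho_err = float(
        np.max(np.abs(res.loadings.T @ res.loadings - np.eye(res.loadings.shape[1])))
    )

    # KDE overlap of identical and well-separated samples
    a = rng.normal(0.0, 1.0, 500)
    same = population.response_overlap(a, a)["overlap"]
    b = rng.normal(10.0, 1.0, 500)
    apart = population.response_overlap(a, b)["overlap"]
    return {
        "z2_chi2_max_diff": max_diff,
        "bh_example_err": bh_exact,
        "binomial_enum_err": binom_err,
        "pca_fraction_sum_err": frac_sum_err,
        "pca_loading_ortho_err": ortho_err,
        "overlap_identical": same,
        "overlap_separated": apart,
    }


def perievent_fidelity_study(seed: int) -> dict:
    """Window means vs brute-force slicing and epoch-count conservation."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        session_duration=600.0,
        zones=_ZONES,
        n_cells=1,
        cell_specs=(CellSpec(_RATE, {"food": 0.5}),),
        transit_s=_TRANSIT,
        noise_sd=_NOISE,
        seed=seed,
    )
    occ, _ = simulate_behavior(cfg)
    traces, _ = simulate_traces(occ, cfg)
    z = traces.zscored().values[0]
    events = perievent.detect_transitions(occ, min_visit_s=1.0)
    raw_events = perievent.detect_transitions(occ, min_visit_s=0.0)
    mat = perievent.extract_epochs(z, traces.rate, events.entries["food"])
    max_err = 0.0
    for name, win in perievent.WINDOWS.items():
        if win.start_s < mat.rel_time[0] or win.end_s > mat.rel_time[-1]:
            continue
        per_epoch, _, _ = perievent.window_mean(mat, win)
        ref = naive.naive_window_mean(mat.values, mat.rel_time, win.start_s, win.end_s)
        both = ~(np.isnan(per_epoch) | np.isnan(ref))
        max_err = max(max_err, float(np.max(np.abs(per_epoch[both] - ref[both]))))
    conserved = mat.n_epochs == events.entries["food"].size
    return {
        "window_mean_max_err": max_err,
        "epochs": int(mat.n_epochs),
        "entries_raw": int(raw_events.entries["food"].size),
        "entries_debounced": int(events.entries["food"].size),
        "count_conserved": bool(conserved),
    }


def pipeline_report(seed: int) -> str:
    """End-to-end run on a fixed config; returns a canonical JSON report
    string so byte-identity across runs can be checked."""
    import json

    binned, design, _, occ = classification_session(seed, 20, lambda i: {"food": 0.3} if i % 2 else {})
    table = cellclass.classify_cells(binned, design, alpha=0.05)
    prop = cellclass.proportion_report(table, "food", "rw")

    cfg = SimConfig(
        session_duration=300.0,
        zones=(ZoneSpec("arena", 30.0),),
        photometry=PhotometrySpec(
            motion_amplitude=0.2, motion_rate=0.5, packet_loss_rate=0.001,
            noise_sd=0.01, signal_rate=0.1, signal_amplitude=0.2,
        ),
        seed=seed,
    )
    occ_p, _ = simulate_behavior(cfg)
    session, _ = simulate_photometry(occ_p, cfg)
    proc = photometry.preprocess(session)

    report = {
        "classification": {
            "n_rows": len(table),
            "labels": table["label"].value_counts().to_dict(),
            "proportions": prop.to_dict(),
            "coef_sum": float(table["coefficient"].sum()),
        },
        "photometry": {
            "z_first10": proc.zscored[:10].tolist(),
            "dff_sum": float(proc.dff.sum()),
            "n_flagged": int(proc.artifact_mask.sum()),
            "baseline_params": {
                k: list(v) for k, v in proc.baseline_params.items()
            },
        },
    }
    return json.dumps(report, sort_keys=True)
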