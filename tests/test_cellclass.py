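"""Linear-model classification: design building, labels, FDR, proportions."""

import numpy as np
import pandas as pd
import pytest

from calzone import cellclass as cc, perievent as pe, statcore, studies
from calzone.session_io import ZoneOccupancy


def occupancy(indicators, rate=30.0):
    return ZoneOccupancy(
        zones=[f"z{i}" for i in range(len(indicators))],
        indicators=np.asarray(indicators, dtype=np.int8),
        rate=rate,
    )


class TestBuildDesign:
    def test_full_session_single_zone_all_ones(self):
        occ = occupancy([np.ones(300, dtype=int)])
        design = cc.build_design(occ)
        assert design["z0"].tolist() == [1.0] * 10

    def test_alternating_visits_alternating_bins(self):
        ind = np.tile(np.concatenate([np.ones(30), np.zeros(30)]), 5).astype(int)
        design = cc.build_design(occupancy([ind]))
        assert design["z0"].tolist() == [1.0, 0.0] * 5

    def test_column_sums_match_brute_force_counts(self, small_session):
        _, occ, _, _, _ = small_session
        design = cc.build_design(occ)
        per_bin = int(occ.rate)
        n_bins = occ.n_samples // per_bin
        for zi, zone in enumerate(occ.zones):
            brute = sum(
                occ.indicators[zi, b * per_bin : (b + 1) * per_bin].mean() > 0.5
                for b in range(n_bins)
            )
            assert design[zone].sum() == brute

    def test_never_occupied_zone_warns_but_kept(self):
        ind = np.zeros((2, 300), dtype=int)
        ind[0, :150] = 1
        occ = occupancy(ind)
        with pytest.warns(UserWarning, match="never occupied"):
            design = cc.build_design(occ)
        assert "z1" in design.columns


class TestClassifyCells:
    def test_noiseless_step_cell_is_excited(self):
        design = pd.DataFrame({"a": [1.0, 0, 1, 0, 1, 0, 1, 0, 1, 0] * 6})
        trace = design["a"].to_numpy()
        table = cc.classify_cells(trace[None, :], design)
        row = table.iloc[0]
        assert row["label"] == "excited"
        assert row["coefficient"] == pytest.approx(1.0)
        assert row["p_raw"] < 1e-12

    def test_sign_flip_swaps_labels_same_p(self, rng):
        design = pd.DataFrame({"a": (rng.random(400) < 0.4).astype(float)})
        trace = 0.4 * design["a"].to_numpy() + rng.normal(0, 1, 400)
        t1 = cc.classify_cells(trace[None, :], design)
        t2 = cc.classify_cells(-trace[None, :], design)
        assert t1.iloc[0]["p_raw"] == pytest.approx(t2.iloc[0]["p_raw"])
        if t1.iloc[0]["label"] != "nonresponsive":
            assert {t1.iloc[0]["label"], t2.iloc[0]["label"]} == {"excited", "inhibited"}

    def test_effect_gate_blocks_small_coefficients(self, rng):
        design = pd.DataFrame({"a": (rng.random(900) < 0.5).astype(float)})
        trace = 0.05 * design["a"].to_numpy() + rng.normal(0, 0.05, 900)
        no_gate = cc.classify_cells(trace[None, :], design, effect_gate=0.0)
        gated = cc.classify_cells(trace[None, :], design, effect_gate=0.1)
        assert no_gate.iloc[0]["label"] == "excited"
        assert gated.iloc[0]["label"] == "nonresponsive"
        assert not gated.iloc[0]["effect_gate_passed"]

    def test_rank_deficient_design_names_columns(self):
        ind = np.zeros((2, 600), dtype=int)
        ind[0, :300] = 1
        ind[1, 300:] = 1  # tiles the session: collinear with the intercept
        occ = occupancy(ind)
        design = cc.build_design(occ)
        with pytest.raises(ValueError, match="rank deficient"):
            cc.classify_cells(np.zeros((1, len(design))), design)

    def test_null_cells_modulated_fraction_bounded(self):
        """Pure-noise cells stay near or below the nominal FDR level."""
        binned, design, _, _ = studies.classification_session(77, 60, lambda i: {})
        table = cc.classify_cells(binned, design, alpha=0.05)
        frac = (table["label"] != "nonresponsive").mean()
        assert frac <= 0.07

    def test_every_pair_gets_exactly_one_label(self, small_session):
        cfg, occ, _, traces, _ = small_session
        z = traces.zscored()
        binned = np.vstack(
            [pe.bin_signal(z.values[i], z.rate) for i in range(z.n_cells)]
        )
        table = cc.classify_cells(binned, cc.build_design(occ))
        assert len(table) == z.n_cells * len(occ.zones)
        assert table["label"].isin(["excited", "inhibited", "nonresponsive"]).all()
        # label consistency with coefficient signs
        assert (table.loc[table["label"] == "excited", "coefficient"] > 0).all()
        assert (table.loc[table["label"] == "inhibited", "coefficient"] < 0).all()
        assert (table["q_adj"] >= table["p_raw"] - 1e-15).all()


class TestPowerMonotonicity:
    def test_recovery_non_decreasing_in_effect_size(self):
        rates = []
        for effect in (0.2, 0.5, 1.0):
            binned, design, _, _ = studies.classification_session(
                5, 40, lambda i, e=effect: {"food": e}
            )
            table = cc.classify_cells(binned, design)
            food = table[table["predictor"] == "food"]
            rates.append((food["label"] == "excited").mean())
        assert rates[0] <= rates[1] + 0.05
        assert rates[1] <= rates[2] + 0.05


class TestStimModulation:
    @staticmethod
    def phase(n_bins, cycle=300):
        return (np.arange(n_bins) // cycle) % 2

    def test_noiseless_lower_during_on_is_inhibited(self):
        phase = self.phase(1200)
        trace = 1.0 - 0.5 * phase
        table = cc.classify_stim_modulation(trace[None, :], phase)
        assert table.iloc[0]["label"] == "inhibited"

    def test_planted_inhibition_recovered(self, rng):
        phase = self.phase(1800)
        traces = rng.normal(0, 1, (40, 1800))
        traces[:20] -= 0.5 * phase  # 20 planted inhibited cells
        traces = (traces - traces.mean(axis=1, keepdims=True)) / traces.std(
            axis=1, ddof=1, keepdims=True
        )
        table = cc.classify_stim_modulation(traces, phase)
        stim = table[table["predictor"] == "stim_on"].reset_index(drop=True)
        recovered = (stim.loc[:19, "label"] == "inhibited").sum()
        assert recovered >= 18

    def test_shuffled_phase_modulated_fraction_near_alpha(self, rng):
        phase = rng.permutation(self.phase(1800))
        traces = rng.normal(0, 1, (100, 1800))
        table = cc.classify_stim_modulation(traces, phase)
        assert (table["label"] != "nonresponsive").mean() <= 0.07

    def test_constant_phase_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cc.classify_stim_modulation(np.zeros((1, 100)), np.ones(100))


class TestProportions:
    @staticmethod
    def toy_table(k1, k2, n=100):
        rows = []
        for i in range(n):
            rows.append({"cell_id": f"c{i}", "predictor": "A",
                         "label": "excited" if i < k1 else "nonresponsive"})
            rows.append({"cell_id": f"c{i}", "predictor": "B",
                         "label": "excited" if i < k2 else "nonresponsive"})
        return pd.DataFrame(rows)

    def test_large_contrast_significant(self):
        rep = cc.proportion_report(self.toy_table(34, 8), "A", "B")
        assert rep.z > 0
        assert rep.p_value < 1e-4
        assert rep.counts == (34, 8)

    def test_equal_counts_z_zero(self):
        rep = cc.proportion_report(self.toy_table(20, 20), "A", "B")
        assert rep.z == 0.0
        assert rep.p_value == pytest.approx(1.0)

    def test_swap_negates_z(self):
        a = cc.proportion_report(self.toy_table(30, 10), "A", "B")
        b = cc.proportion_report(self.toy_table(30, 10), "B", "A")
        assert a.z == pytest.approx(-b.z)
        assert a.p_value == pytest.approx(b.p_value)

    def test_missing_predictor_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            cc.proportion_report(self.toy_table(5, 5), "A", "C")

    def test_chi2_identical_proportions_near_zero(self):
        res = cc.proportion_across_conditions((30, 70), (30, 70), (30, 70))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_equals_z_squared_on_2x2(self):
        res = cc.proportion_across_conditions((34, 66), (8, 92))
        z = statcore.two_proportion_z(34, 100, 8, 100).statistic
        assert res.statistic == pytest.approx(z**2, abs=1e-10)

    def test_hand_computed_pearson(self):
        res = cc.proportion_across_conditions((60, 40), (40, 60))
        assert res.statistic == pytest.approx(8.0, abs=1e-12)
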