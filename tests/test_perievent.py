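"""Binning, transition detection, epoch extraction and window means."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from calzone import naive, perievent as pe
from calzone.session_io import ZoneOccupancy


def occupancy_from(indicator, rate=10.0, zone="z"):
    ind = np.asarray(indicator, dtype=np.int8)[None, :]
    return ZoneOccupancy(zones=[zone], indicators=ind, rate=rate)


class TestBinSignal:
    def test_partial_final_bin_dropped(self):
        x = np.arange(25.0)
        out = pe.bin_signal(x, rate=10.0, bin_s=1.0)
        assert out.shape == (2,)
        assert out[0] == pytest.approx(np.mean(np.arange(10)))

    def test_constant_trace_constant_bins(self):
        assert np.allclose(pe.bin_signal(np.full(40, 2.5), 10.0), 2.5)

    def test_matches_naive_slicing(self, rng):
        x = rng.normal(size=157)
        assert np.allclose(
            pe.bin_signal(x, 10.0), naive.naive_bin_signal(x, 10.0), atol=1e-12
        )

    def test_incommensurate_bin_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            pe.bin_signal(np.ones(30), rate=10.0, bin_s=0.25)


class TestDetectTransitions:
    def test_simple_entries_and_exits(self):
        occ = occupancy_from([0, 0, 1, 1, 0, 1], rate=1.0)
        ev = pe.detect_transitions(occ, min_visit_s=0.0)
        assert ev.entries["z"].tolist() == [2.0, 5.0]
        assert ev.exits["z"].tolist() == [4.0, 6.0]  # open visit closed at end

    def test_all_zero_indicator_empty(self):
        ev = pe.detect_transitions(occupancy_from([0, 0, 0, 0]), min_visit_s=0.0)
        assert ev.entries["z"].size == 0

    def test_flicker_removed_by_debounce(self):
        # 0.5-s exit inside a long visit at 10 Hz
        ind = [1] * 30 + [0] * 5 + [1] * 30
        ev = pe.detect_transitions(occupancy_from(ind), min_visit_s=1.0)
        assert ev.n_visits("z") == 1
        ev_raw = pe.detect_transitions(occupancy_from(ind), min_visit_s=0.0)
        assert ev_raw.n_visits("z") == 2

    def test_short_visit_dropped(self):
        ind = [0] * 30 + [1] * 5 + [0] * 30
        ev = pe.detect_transitions(occupancy_from(ind), min_visit_s=1.0)
        assert ev.n_visits("z") == 0


class TestExtractEpochs:
    def test_interior_event_untruncated(self, rng):
        x = rng.normal(size=2000)
        mat = pe.extract_epochs(x, 10.0, np.array([100.0]))
        assert mat.values.shape == (1, 201)
        assert not mat.truncated[0]
        assert np.array_equal(mat.values[0], x[950:1151])

    def test_early_event_flagged_truncated_never_zero_filled(self, rng):
        x = rng.normal(size=500)
        mat = pe.extract_epochs(x, 10.0, np.array([2.0]))
        assert mat.truncated[0]
        assert np.isnan(mat.values[0, :30]).all()
        assert np.array_equal(mat.values[0, 30:], x[: 201 - 30])

    def test_no_events_gives_empty_matrix(self):
        mat = pe.extract_epochs(np.zeros(100), 10.0, np.array([]))
        assert mat.n_epochs == 0


class TestWindowRegistry:
    def test_named_offsets_pinned(self):
        expect = {
            "pre": (-3.0, 0.0),
            "post": (0.0, 3.0),
            "peri_entry": (-1.0, 1.0),
            "post_2_4": (2.0, 4.0),
            "post_4_6": (4.0, 6.0),
            "approach": (-6.0, -3.0),
        }
        assert {k: (w.start_s, w.end_s) for k, w in pe.WINDOWS.items()} == expect


class TestWindowMean:
    def make_matrix(self, values):
        values = np.atleast_2d(values)
        n = values.shape[1]
        rel = (np.arange(n) - 50) / 10.0  # -5 .. +15 grid at 10 Hz
        return pe.PeriEventMatrix(
            values=values,
            rel_time=rel,
            entry_times=np.zeros(values.shape[0]),
            truncated=np.zeros(values.shape[0], dtype=bool),
        )

    def test_constant_epoch_means_constant(self):
        mat = self.make_matrix(np.ones((3, 201)))
        for w in pe.WINDOWS.values():
            if w.start_s >= -5.0 and w.end_s <= 15.0:
                _, overall, _ = pe.window_mean(mat, w)
                assert overall == pytest.approx(1.0)

    def test_step_epoch_pre_zero_post_one(self):
        row = np.concatenate([np.zeros(50), np.ones(151)])
        mat = self.make_matrix(row)
        _, pre, _ = pe.window_mean(mat, pe.WINDOWS["pre"])
        _, post, _ = pe.window_mean(mat, pe.WINDOWS["post"])
        assert pre == 0.0
        assert post == 1.0

    def test_matches_naive_index_oracle(self, rng):
        # wider -10..+15 s grid so the food-approach window also fits
        vals = rng.normal(size=(7, 251))
        rel = (np.arange(251) - 100) / 10.0
        mat = pe.PeriEventMatrix(
            values=vals,
            rel_time=rel,
            entry_times=np.zeros(7),
            truncated=np.zeros(7, dtype=bool),
        )
        for w in pe.WINDOWS.values():
            per_epoch, _, _ = pe.window_mean(mat, w)
            ref = naive.naive_window_mean(mat.values, mat.rel_time, w.start_s, w.end_s)
            assert np.allclose(per_epoch, ref, atol=1e-12)

    def test_truncated_epochs_excluded_and_counted(self, rng):
        vals = rng.normal(size=(3, 201))
        vals[1, :40] = np.nan
        mat = self.make_matrix(vals)
        per_epoch, _, excluded = pe.window_mean(mat, pe.WINDOWS["pre"])
        assert excluded == 1
        assert np.isnan(per_epoch[1])

    def test_window_outside_epoch_rejected(self):
        mat = self.make_matrix(np.ones((2, 201)))
        with pytest.raises(ValueError, match="outside"):
            pe.window_mean(mat, pe.WindowSpec("too_late", 14.0, 17.0))

    @given(
        a=st.floats(-3, 3, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
    )
    def test_linearity(self, a, b):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(4, 201))
        m1 = self.make_matrix(base)
        m2 = self.make_matrix(a * base + b)
        for w in (pe.WINDOWS["pre"], pe.WINDOWS["post_2_4"]):
            _, v1, _ = pe.window_mean(m1, w)
            _, v2, _ = pe.window_mean(m2, w)
            assert v2 == pytest.approx(a * v1 + b, abs=1e-9 * (1 + abs(a) + abs(b)))


class TestSmoothPerievent:
    def make_matrix(self, values):
        values = np.atleast_2d(values)
        rel = (np.arange(values.shape[1]) - 50) / 10.0
        return pe.PeriEventMatrix(
            values=values,
            rel_time=rel,
            entry_times=np.zeros(values.shape[0]),
            truncated=np.zeros(values.shape[0], dtype=bool),
        )

    def test_constant_data_constant_curve(self):
        mat = self.make_matrix(np.full((4, 201), 2.0))
        fitted, sem = pe.smooth_perievent(mat, span=0.3)
        assert np.allclose(fitted, 2.0, atol=1e-9)
        assert np.allclose(sem, 0.0, atol=1e-12)

    def test_linear_ramp_reproduced_on_interior(self):
        rel = (np.arange(201) - 50) / 10.0
        mat = self.make_matrix(np.vstack([2.0 * rel + 1.0] * 3))
        fitted, _ = pe.smooth_perievent(mat, span=0.3)
        interior = slice(20, 180)
        assert np.allclose(fitted[interior], (2.0 * rel + 1.0)[interior], atol=1e-6)

    def test_span_one_equals_global_quadratic(self, rng):
        vals = rng.normal(size=(5, 201))
        mat = self.make_matrix(vals)
        fitted, _ = pe.smooth_perievent(mat, span=1.0)
        rel = mat.rel_time
        tt = np.tile(rel, 5)
        yy = vals.ravel()
        coef = np.polyfit(tt, yy, 2)
        assert np.allclose(fitted, np.polyval(coef, rel), atol=1e-8)

    def test_single_epoch_rejected(self):
        mat = self.make_matrix(np.ones((1, 201)))
        with pytest.raises(ValueError, match="2 epochs"):
            pe.smooth_perievent(mat)

    def test_tiny_span_rejected(self):
        mat = self.make_matrix(np.ones((3, 201)))
        with pytest.raises(ValueError, match="span"):
            pe.smooth_perievent(mat, span=0.001)


def test_epoch_count_conservation(small_session):
    """Rows of the epoch matrix equal detected entries after debouncing."""
    cfg, occ, _, traces, _ = small_session
    events = pe.detect_transitions(occ, min_visit_s=1.0)
    z = traces.zscored().values[0]
    for zone in occ.zones:
        mat = pe.extract_epochs(z, traces.rate, events.entries[zone])
        assert mat.n_epochs == events.entries[zone].size
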