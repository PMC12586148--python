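"""Photometry stage contracts and naive-oracle equivalence."""

import numpy as np
import pytest

from calzone import naive, photometry as ph
from calzone.photometry import PhotometrySession
from calzone.synthgen import PhotometrySpec, SimConfig, ZoneSpec, simulate_behavior, simulate_photometry


def make_session(primary, isobestic=None, rate=30.0):
    primary = np.asarray(primary, dtype=float)
    if isobestic is None:
        isobestic = np.zeros_like(primary)
    return PhotometrySession(primary=primary, isobestic=isobestic, rate=rate)


class TestTrim:
    def test_default_trim_sample_count(self):
        s = make_session(np.arange(3000.0))
        trimmed = ph.trim_startup(s, 5.0)
        assert trimmed.n_samples == 2850
        assert trimmed.primary[0] == 150.0
        assert trimmed.t0 == 5.0

    def test_zero_trim_is_identity(self):
        s = make_session(np.arange(300.0))
        assert np.array_equal(ph.trim_startup(s, 0.0).primary, s.primary)

    def test_too_short_session_rejected(self):
        s = make_session(np.arange(120.0))  # 4 s at 30 Hz
        with pytest.raises(ValueError, match="trim"):
            ph.trim_startup(s, 5.0)


class TestArtifactInterpolation:
    def test_single_spike_on_constant_flagged_and_restored(self, rng):
        x = np.full(900, 2.0) + rng.normal(0, 1e-6, 900)
        x[450] += 100.0
        cleaned, mask = ph.interpolate_artifacts(x, 30.0)
        assert mask[450]
        assert mask.sum() == 1
        assert cleaned[450] == pytest.approx(2.0, abs=1e-4)

    def test_gaussian_noise_flag_rate_below_normal_tail_bound(self, rng):
        x = rng.normal(size=30 * 600)
        _, mask = ph.interpolate_artifacts(x, 30.0)
        # fence at Q3 + 4*IQR ~ 6.07 sd: two-sided tail mass < 1e-8 << 0.1%
        assert mask.mean() < 0.001

    def test_planted_packet_loss_recovered(self):
        cfg = SimConfig(
            session_duration=600.0,
            zones=(ZoneSpec("arena", 30.0),),
            photometry=PhotometrySpec(packet_loss_rate=0.002, noise_sd=0.01),
            seed=4,
        )
        occ, _ = simulate_behavior(cfg)
        session, gt = simulate_photometry(occ, cfg)
        cleaned, mask = ph.interpolate_artifacts(session.primary, session.rate)
        planted = gt.artifact_mask
        assert np.all(mask[planted])  # recovered mask contains the planted one
        clean_signal = gt.bleach_primary
        dev = np.abs(cleaned[planted] - clean_signal[planted])
        assert dev.max() < 5 * 0.01 + 1e-6

    def test_idempotent_at_default_k(self, rng):
        x = rng.normal(size=30 * 120)
        x[100] += 50
        cleaned, _ = ph.interpolate_artifacts(x, 30.0)
        _, mask2 = ph.interpolate_artifacts(cleaned, 30.0)
        assert mask2.sum() == 0

    def test_matches_naive_oracle(self, rng):
        x = rng.normal(size=400)
        x[50] += 30
        x[200:203] -= 25
        fast_clean, fast_mask = ph.interpolate_artifacts(x, 10.0)
        ref_clean, ref_mask = naive.naive_interpolate_artifacts(x, 10.0)
        assert np.array_equal(fast_mask, ref_mask)
        assert np.allclose(fast_clean, ref_clean, atol=1e-8)


class TestMovingAverage:
    def test_impulse_spread_with_truncated_edges(self):
        out = ph.moving_average(np.array([0.0, 0, 10, 0, 0]), rate=3.0, window_s=1.0)
        assert np.allclose(out, [0, 10 / 3, 10 / 3, 10 / 3, 0])

    def test_constant_series_unchanged(self):
        x = np.full(100, 3.7)
        assert np.allclose(ph.moving_average(x, 30.0), x)

    def test_matches_naive_oracle(self, rng):
        x = rng.normal(size=500)
        for w in (0.5, 1.0, 2.0):
            assert np.allclose(
                ph.moving_average(x, 30.0, w),
                naive.naive_moving_average(x, 30.0, w),
                atol=1e-8,
            )


class TestDoubleExponential:
    def test_recovers_planted_curve(self, rng):
        t = np.arange(30 * 600) / 30.0
        clean = 5.0 * np.exp(-0.01 * t) + 2.0 * np.exp(-0.0005 * t)
        noisy = clean + rng.normal(0, 0.01, t.size)
        _, curve = ph.fit_double_exponential(noisy, 30.0)
        assert np.sqrt(np.mean((curve - clean) ** 2)) < 0.05
        assert np.all(np.diff(curve) <= 1e-12)  # monotone decreasing

    def test_constant_series_absorbed_by_slow_term(self):
        x = np.full(600, 4.2)
        _, curve = ph.fit_double_exponential(x, 30.0)
        assert np.allclose(curve, 4.2, atol=1e-3)

    def test_nested_model_beats_single_exponential(self, rng):
        t = np.arange(30 * 300) / 30.0
        single = 3.0 * np.exp(-0.02 * t)
        noisy = single + rng.normal(0, 0.01, t.size)
        _, curve = ph.fit_double_exponential(noisy, 30.0)
        # best single-exponential fit by coarse grid + refinement
        from scipy.optimize import curve_fit

        p, _ = curve_fit(
            lambda tt, a, b: a * np.exp(-b * tt), t, noisy, p0=(3.0, 0.02)
        )
        res_single = np.sum((p[0] * np.exp(-p[1] * t) - noisy) ** 2)
        res_double = np.sum((curve - noisy) ** 2)
        assert res_double <= res_single * (1 + 1e-6)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="100"):
            ph.fit_double_exponential(np.ones(50), 30.0)


class TestMotionCorrection:
    def test_exact_linear_relation_cancels(self, rng):
        iso = rng.normal(size=300)
        primary = 2.0 * iso + 3.0
        corrected, (slope, intercept) = ph.correct_motion(primary, iso)
        assert slope == pytest.approx(2.0)
        assert np.allclose(corrected, 0.0, atol=1e-12)

    def test_independent_channels_just_demean(self, rng):
        primary = rng.normal(size=20000)
        iso = rng.normal(size=20000)
        corrected, (slope, _) = ph.correct_motion(primary, iso)
        assert abs(slope) < 0.05
        assert np.allclose(corrected, primary - primary.mean(), atol=0.1)

    def test_constant_isobestic_warns_slope_zero(self, rng):
        primary = rng.normal(size=200)
        with pytest.warns(UserWarning, match="constant"):
            corrected, (slope, _) = ph.correct_motion(primary, np.ones(200))
        assert slope == 0.0

    def test_matches_naive_oracle(self, rng):
        p = rng.normal(size=400)
        i = 0.5 * p + rng.normal(size=400)
        assert np.allclose(
            ph.correct_motion(p, i)[0], naive.naive_correct_motion(p, i), atol=1e-8
        )


class TestDff:
    def test_zero_corrected_gives_zero(self):
        assert np.all(ph.compute_dff(np.zeros(10), np.ones(10)) == 0.0)

    def test_proportional_signal_gives_constant(self):
        base = np.linspace(5, 1, 50)
        assert np.allclose(ph.compute_dff(0.1 * base, base), 0.1)

    def test_algebraic_inverse(self, rng):
        base = np.abs(rng.normal(5, 1, 200)) + 1.0
        corrected = rng.normal(size=200)
        dff = ph.compute_dff(corrected, base)
        assert np.allclose(dff * base, corrected, atol=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ph.compute_dff(np.ones(5), np.array([1.0, 0.0, 1, 1, 1]))


class TestPreprocess:
    def make_synth(self, seed=8, **photo_kw):
        cfg = SimConfig(
            session_duration=300.0,
            zones=(ZoneSpec("arena", 30.0),),
            photometry=PhotometrySpec(**photo_kw),
            seed=seed,
        )
        occ, _ = simulate_behavior(cfg)
        return simulate_photometry(occ, cfg)

    def test_no_signal_session_has_no_extreme_z(self):
        session, _ = self.make_synth(noise_sd=0.02, motion_amplitude=0.1)
        proc = ph.preprocess(session)
        assert np.max(np.abs(proc.zscored)) < 5.0

    def test_zscore_normalization_exact(self):
        session, _ = self.make_synth(noise_sd=0.02, signal_rate=0.1, signal_amplitude=0.2)
        proc = ph.preprocess(session)
        assert abs(proc.zscored.mean()) < 1e-9
        assert abs(proc.zscored.std(ddof=1) - 1.0) < 1e-9

    def test_deterministic(self):
        session, _ = self.make_synth(noise_sd=0.02, motion_amplitude=0.2, packet_loss_rate=0.001)
        p1 = ph.preprocess(session)
        p2 = ph.preprocess(session)
        assert np.array_equal(p1.zscored, p2.zscored)

    def test_planted_transients_raise_perionset_mean(self):
        session, gt = self.make_synth(
            noise_sd=0.01, signal_rate=0.05, signal_amplitude=0.5
        )
        proc = ph.preprocess(session)
        rate = session.rate
        onsets = gt.signal_onsets[gt.signal_onsets > 6.0] - 5.0  # shift for trim
        z = proc.zscored
        vals = []
        for o in onsets:
            i = int(o * rate)
            if i + rate <= z.size:
                vals.append(z[i : i + int(rate)].mean())
        assert np.mean(vals) > z.mean()

    def test_stage_outputs_retained_in_order(self):
        session, _ = self.make_synth(noise_sd=0.02)
        proc = ph.preprocess(session)
        keys = list(proc.stage_outputs)
        assert keys.index("trimmed_primary") < keys.index("deartifacted_primary")
        assert keys.index("smoothed_primary") < keys.index("detrended_primary")
        assert keys.index("motion_corrected") < keys.index("dff")
        assert keys[-1] == "zscored"
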