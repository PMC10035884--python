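"""Synthetic-subject generators: spectra, calibration, shooter behavior."""

import numpy as np
import pytest
from scipy.signal import periodogram

from fmtheta import offline, protocol, synth
from fmtheta.types import SignalSegment, SubjectParams

from conftest import make_enemy_run, make_friendly_run


class TestBackground:
    def test_zero_scale_gives_all_zero_samples(self):
        seg = synth.generate_background(2.0, 512.0, 1.0, scale=0.0, seed=1)
        assert np.all(seg.samples == 0)

    def test_spectral_slope_matches_requested_exponent(self):
        # log-log periodogram regression over 1-100 Hz recovers the slope
        seg = synth.generate_background(60.0, 2048.0, 1.0, scale=10.0, seed=7)
        f, p = periodogram(seg.samples, fs=2048.0)
        m = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_same_seed_bit_identical(self):
        a = synth.generate_background(1.0, 512.0, 1.0, 5.0, seed=42)
        b = synth.generate_background(1.0, 512.0, 1.0, 5.0, seed=42)
        assert np.array_equal(a.samples, b.samples)
        c = synth.generate_background(1.0, 512.0, 1.0, 5.0, seed=43)
        assert not np.array_equal(a.samples, c.samples)

    @pytest.mark.parametrize("dur,fs", [(-1.0, 512.0), (1.0, 0.0)])
    def test_invalid_arguments_rejected(self, dur, fs):
        with pytest.raises(ValueError):
            synth.generate_background(dur, fs, 1.0, 1.0, seed=0)


class TestBandOscillation:
    def test_zero_amplitude_is_identity(self):
        base = synth.generate_background(1.0, 512.0, 1.0, 5.0, seed=0)
        out = synth.add_band_oscillation(base, 6.0, 0.0)
        assert np.array_equal(out.samples, base.samples)

    def test_sinusoid_band_power_closed_form(self):
        # amplitude a on zero background: band power a^2/2 within 5%
        zero = SignalSegment(np.zeros(2048 * 2), 2048.0)
        a = 10.0
        seg = synth.add_band_oscillation(zero, 6.0, a)
        bp = offline.welch_band_power(seg.samples, 2048.0, statistic="integral")
        assert bp.power == pytest.approx(a**2 / 2, rel=0.05)

    def test_doubling_amplitude_quadruples_power(self):
        zero = SignalSegment(np.zeros(2048 * 2), 2048.0)
        p1 = offline.welch_band_power(
            synth.add_band_oscillation(zero, 6.0, 5.0).samples, 2048.0,
            statistic="integral").power
        p2 = offline.welch_band_power(
            synth.add_band_oscillation(zero, 6.0, 10.0).samples, 2048.0,
            statistic="integral").power
        assert p2 / p1 == pytest.approx(4.0, rel=0.02)

    def test_input_segment_unchanged(self):
        base = synth.generate_background(1.0, 512.0, 1.0, 5.0, seed=0)
        before = base.samples.copy()
        synth.add_band_oscillation(base, 6.0, 3.0)
        assert np.array_equal(base.samples, before)

    def test_nyquist_rejected(self):
        zero = SignalSegment(np.zeros(512), 512.0)
        with pytest.raises(ValueError):
            synth.add_band_oscillation(zero, 256.0, 1.0)


class TestArtifacts:
    def test_no_onsets_is_identity(self):
        base = synth.generate_background(2.0, 512.0, 1.0, 5.0, seed=0)
        out, ivals = synth.inject_artifacts(base, [], peak_uV=150.0)
        assert ivals == []
        assert np.array_equal(out.samples, base.samples)

    def test_threshold_scan_flags_inside_interval_only(self):
        # clean background scaled below 75 uV; 150 uV pulse detectable
        base = synth.generate_background(10.0, 512.0, 1.0, 5.0, seed=1)
        out, ivals = synth.inject_artifacts(base, [4.0], peak_uV=150.0, dur_s=0.25)
        (lo, hi), = ivals
        over = np.abs(out.samples) > 75.0
        assert over[lo:hi].any()
        assert not np.delete(over, np.s_[lo:hi]).any()
        assert np.abs(out.samples[lo:hi]).max() >= 150.0 * 0.999

    def test_two_onsets_disjoint_ascending(self):
        base = synth.generate_background(10.0, 512.0, 1.0, 1.0, seed=1)
        _, ivals = synth.inject_artifacts(base, [6.0, 2.0], peak_uV=100.0, dur_s=0.2)
        assert len(ivals) == 2
        assert ivals[0][1] <= ivals[1][0]

    def test_overlapping_intervals_merge_with_warning(self):
        base = synth.generate_background(5.0, 512.0, 1.0, 1.0, seed=1)
        with pytest.warns(UserWarning, match="merged"):
            _, ivals = synth.inject_artifacts(base, [1.0, 1.1], peak_uV=100.0, dur_s=0.25)
        assert len(ivals) == 1

    def test_subthreshold_peak_rejected(self):
        base = synth.generate_background(2.0, 512.0, 1.0, 1.0, seed=1)
        with pytest.raises(ValueError):
            synth.inject_artifacts(base, [1.0], peak_uV=50.0)


def _interval_band_powers(record, kinds=("mod/Up", "mod/Down", "rest")):
    out = {k: [] for k in kinds}
    for onset, dur, code in record.events:
        if code in out:
            x = record.segment.samples[onset : onset + dur]
            out[code].append(offline.welch_band_power(x, record.fs).power)
    return out


class TestNFSession:
    def test_null_subject_modulation_equals_rest(self, alt_session):
        p = SubjectParams(subject_id="N1", group="ALT", up_gain=1.0, down_gain=1.0,
                          artifact_rate=0.0)
        rec = synth.simulate_nf_session(p, alt_session, seed=2)
        bp = _interval_band_powers(rec)
        mod = np.mean(bp["mod/Up"] + bp["mod/Down"])
        rest = np.mean(bp["rest"])
        assert abs(10 * np.log10(mod / rest)) < 0.5

    def test_up_gain_two_is_three_db_above_rest(self, alt_session, alt_params):
        rec = synth.simulate_nf_session(
            alt_params.__class__(**{**alt_params.__dict__, "artifact_rate": 0.0}),
            alt_session, seed=2)
        bp = _interval_band_powers(rec)
        up_db = 10 * np.log10(np.mean(bp["mod/Up"]) / np.mean(bp["rest"]))
        assert up_db == pytest.approx(10 * np.log10(2.0), abs=0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_alt_up_blocks_always_exceed_down_blocks(self, seed):
        # compact sessions (2 trials/block) keep the Monte-Carlo check fast
        p = SubjectParams(subject_id="A", group="ALT", up_gain=2.0, down_gain=0.5,
                          artifact_rate=0.0)
        goals = protocol.assign_block_goals("ALT", seed)
        blocks = [protocol.NFBlock(i + 1, g, n_trials=2) for i, g in enumerate(goals)]
        session = protocol.NFSession(1, blocks)
        rec = synth.simulate_nf_session(p, session, seed=seed)
        per_block: dict[tuple[int, str], list[float]] = {}
        intervals = list(session.intervals())
        for iv in intervals:
            if iv.kind != "modulation":
                continue
            lo = int(iv.start_s * rec.fs)
            hi = int(iv.end_s * rec.fs)
            power = offline.welch_band_power(
                rec.segment.samples[lo:hi], rec.fs).power
            per_block.setdefault((iv.block_index, iv.goal.value), []).append(power)
        ups = [np.mean(v) for (b, g), v in per_block.items() if g == "Up"]
        downs = [np.mean(v) for (b, g), v in per_block.items() if g == "Down"]
        assert min(ups) > max(downs)

    def test_session_trend_shifts_power_in_db(self, alt_params, alt_session):
        p = SubjectParams(subject_id="T", group="INC", down_gain=1.0, up_gain=1.0,
                          session_trend=2.0, artifact_rate=0.0)
        s1 = protocol.build_session_timeline(1, protocol.assign_block_goals("INC", 0))
        s3 = protocol.build_session_timeline(3, protocol.assign_block_goals("INC", 0))
        r1 = synth.simulate_nf_session(p, s1, seed=5)
        r3 = synth.simulate_nf_session(p, s3, seed=5)
        m1 = np.mean(_interval_band_powers(r1)["mod/Up"])
        m3 = np.mean(_interval_band_powers(r3)["mod/Up"])
        assert 10 * np.log10(m3 / m1) == pytest.approx(4.0, abs=0.6)

    def test_determinism(self, alt_params, alt_session):
        a = synth.simulate_nf_session(alt_params, alt_session, seed=9)
        b = synth.simulate_nf_session(alt_params, alt_session, seed=9)
        assert np.array_equal(a.segment.samples, b.segment.samples)
        assert a.events == b.events


class TestShooter:
    def test_zero_commission_prob_never_fires_at_friendlies(self, alt_params):
        p = SubjectParams(**{**alt_params.__dict__, "commission_prob": 0.0})
        trials = synth.simulate_shooter(p, make_friendly_run(900.0, 200), seed=1)
        assert all(t.outcome.value == "correct_withhold" for t in trials)

    def test_full_commission_prob_always_fires(self, alt_params):
        p = SubjectParams(**{**alt_params.__dict__, "commission_prob": 1.0})
        trials = synth.simulate_shooter(p, make_friendly_run(900.0, 100), seed=1)
        assert all(t.outcome.value == "commission" for t in trials)

    def test_hit_rate_at_tet50_is_half(self, alt_params):
        # binomial oracle: 1000 trials at TET = tet50; 3 SE band around 50%
        trials = synth.simulate_shooter(alt_params, make_enemy_run(750.0, 1000), seed=5)
        rate = np.mean([t.hit for t in trials])
        se = np.sqrt(0.5 * 0.5 / 1000)
        assert abs(rate - 0.5) < 3 * se

    def test_hit_rate_at_tet90_is_ninety_pct(self, alt_params):
        trials = synth.simulate_shooter(alt_params, make_enemy_run(1100.0, 1000), seed=6)
        rate = np.mean([t.hit for t in trials])
        se = np.sqrt(0.9 * 0.1 / 1000)
        assert abs(rate - 0.9) < 3 * se

    def test_omission_iff_latency_exceeds_exposure(self, alt_params):
        trials = synth.simulate_shooter(alt_params, make_enemy_run(300.0, 300), seed=2)
        for t in trials:
            if t.outcome.value == "omission":
                assert t.shot_times_ms == [] and t.rt_ms is None
            else:
                assert t.rt_ms is not None and t.rt_ms <= t.target.tet_ms


class TestCohortOutcomes:
    def test_table_shape_and_coding(self):
        subs = [SubjectParams(subject_id=f"S{i}", group="ALT") for i in range(4)]
        tab = synth.simulate_cohort_outcomes(subs, n_sessions=3, n_blocks=6, seed=0)
        assert len(tab) == 4 * 3 * 6
        assert set(tab.columns) == {"subject", "group", "session", "block",
                                    "modulation", "y"}
        assert set(tab["modulation"].unique()) <= {0, 1}

    def test_session_trend_recovered_by_ols(self):
        subs = [SubjectParams(subject_id="S0", group="INC", session_trend=1.0,
                              down_gain=1.0)]
        tab = synth.simulate_cohort_outcomes(
            subs, n_sessions=5, residual_sd_db=0.01, slope_sd_db=0.0, seed=3)
        slope = np.polyfit(tab["session"], tab["y"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)
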