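import numpy as np
import pytest
from scipy import signal as sps

import pulmosense as ps
from pulmosense.simulate import _IP_CHANNEL_PROFILE


class TestBreathTrain:
    def test_breath_count_matches_rate(self):
        params = ps.BreathTrainParams(duration_s=300.0, rr_mean_bpm=20.0,
                                      rr_jitter_cv=0.0, seed=1)
        _, truth = ps.make_breath_train(params)
        assert abs(len(truth) - 100) <= 1

    def test_same_seed_reproduces_waveform(self):
        params = ps.BreathTrainParams(duration_s=60.0, seed=7)
        s1, t1 = ps.make_breath_train(params)
        s2, t2 = ps.make_breath_train(params)
        assert np.array_equal(s1.values, s2.values)
        assert [(b.onset, b.peak, b.end) for b in t1] == \
               [(b.onset, b.peak, b.end) for b in t2]

    def test_truths_ordered_and_contiguous(self, quiet_train):
        _, series, truth = quiet_train
        for a, b in zip(truth[:-1], truth[1:]):
            assert a.onset < a.peak < a.end <= b.onset
        assert truth[0].onset >= 0
        assert truth[-1].end <= series.duration

    def test_ti_te_ratio_respected(self):
        params = ps.BreathTrainParams(duration_s=120.0, ti_te_ratio=0.5, seed=2)
        _, truth = ps.make_breath_train(params)
        ratios = [(b.peak - b.onset) / (b.end - b.peak) for b in truth]
        assert np.allclose(ratios, 0.5, atol=1e-9)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            ps.make_breath_train(ps.BreathTrainParams(duration_s=2.0,
                                                      rr_mean_bpm=10.0))

    @pytest.mark.parametrize("field,value", [
        ("rr_mean_bpm", 0.0), ("rr_mean_bpm", 150.0),
        ("ti_te_ratio", -1.0), ("sample_rate_hz", 0.1),
    ])
    def test_invalid_params_rejected(self, field, value):
        params = ps.BreathTrainParams(**{field: value})
        with pytest.raises(ValueError):
            params.validate()


class TestCSR:
    def test_five_cycles_give_five_envelope_maxima(self, csr_signal):
        csr, mod, _ = csr_signal
        env = ps.csr_envelope(np.arange(0, 240, 1 / 16), csr)
        maxima, _ = sps.find_peaks(env, height=0.9)
        assert len(maxima) == csr.n_cycles == 5

    def test_apnea_segments_are_silent(self, csr_signal):
        csr, mod, _ = csr_signal
        env = ps.csr_envelope(mod.times(), csr)
        apnea = env < 1e-12
        assert apnea.any()
        assert np.abs(mod.values[apnea]).max() <= 0.05  # noise sd of fixture

    def test_apnea_truth_flags(self, csr_signal):
        csr, _, truth = csr_signal
        flagged = [b for b in truth if b.in_apnea]
        assert flagged
        # apnea = envelope below 1 % of the cycle maximum; for the raised
        # cosine that region ends arccos(0.98)/(2 pi) of the breathing part
        # past the silent stretch (closed form, independent of the generator)
        T, a = csr.cycle_length_s, csr.apnea_fraction * csr.cycle_length_s
        b_len = T - a
        margin = np.arccos(0.98) * b_len / (2 * np.pi)
        lo, hi = a / 2 + margin, T - a / 2 - margin
        for b in truth:
            phases = np.mod(np.linspace(b.onset, b.end, 200), T)
            touches = bool(np.any((phases < lo) | (phases > hi)))
            assert b.in_apnea == touches

    def test_cycle_shorter_than_two_breaths_rejected(self, quiet_train):
        _, series, truth = quiet_train
        with pytest.raises(ValueError, match="cycle"):
            ps.apply_csr_envelope(series, truth,
                                  ps.CSRParams(cycle_length_s=4.0))


class TestColeModel:
    def test_low_frequency_limit_is_r0(self):
        cole = ps.ColeParams(r0=60, rinf=40, tau_c=2e-6, alpha=0.7)
        z = ps.cole_impedance(cole, 1e-3)
        assert z.real == pytest.approx(60.0, abs=1e-3)
        assert z.imag == pytest.approx(0.0, abs=1e-3)

    def test_high_frequency_limit_is_rinf(self):
        cole = ps.ColeParams(r0=60, rinf=40, tau_c=2e-6, alpha=0.7)
        z = ps.cole_impedance(cole, 1e12)
        assert z.real == pytest.approx(40.0, abs=1e-2)

    def test_characteristic_frequency_midpoint(self):
        cole = ps.ColeParams(r0=60, rinf=40, tau_c=2e-6, alpha=1.0)
        z = ps.cole_impedance(cole, 1.0 / (2 * np.pi * cole.tau_c))
        assert z.real == pytest.approx((60 + 40) / 2, rel=1e-9)

    def test_resistance_decreases_with_frequency(self):
        cole = ps.ColeParams(alpha=1.0)
        f = np.geomspace(1e2, 1e7, 50)
        r = ps.cole_impedance(cole, f).real
        assert np.all(np.diff(r) < 0)

    def test_params_for_k_hits_target(self):
        for k in (1.1, 1.27, 1.32, 1.5):
            cole = ps.cole_params_for_k(k)
            z = ps.cole_impedance(cole, np.array([5000.0, 150000.0]))
            assert z[0].real / z[1].real == pytest.approx(k, rel=1e-12)


class TestBISweeps:
    def test_noiseless_sweeps_identical_to_curve(self):
        cole = ps.ColeParams()
        sweeps = ps.make_bis_sweeps(cole, n_sweeps=5, noise_sd=0.0, seed=0)
        clean = ps.cole_impedance(cole, sweeps[0].freqs)
        for s in sweeps:
            assert np.allclose(s.impedances, clean)

    def test_noise_sd_recovered_across_sweeps(self):
        sweeps = ps.make_bis_sweeps(n_sweeps=30, noise_sd=0.5, seed=3)
        r = np.array([s.impedances.real for s in sweeps])
        sd = r.std(axis=0, ddof=1)
        assert np.all(sd > 0.35) and np.all(sd < 0.65)  # 0.5 +/- 30 %

    def test_default_session_has_thirty_sweeps(self):
        assert len(ps.make_bis_sweeps(seed=0)) == 30

    def test_sweep_timestamps_every_two_seconds(self):
        sweeps = ps.make_bis_sweeps(n_sweeps=4, seed=0)
        assert np.allclose(np.diff([s.timestamp for s in sweeps]), 2.0)


class TestLungAudio:
    def test_crackle_count_and_placement(self, quiet_train):
        _, _, truth = quiet_train
        short = [b for b in truth if b.end <= 60]
        params = ps.LungAudioParams(n_crackles=12)
        _, events = ps.make_lung_audio(short, params, seed=9)
        crackles = [e for e in events if e.kind == "crackle"]
        assert len(crackles) == 12
        for c in crackles:
            assert any(b.onset <= c.time <= b.peak for b in short), \
                "crackle outside inspiratory intervals"
            assert c.center_freq_hz > 650

    def test_inspiration_louder_than_silence(self, quiet_train):
        _, _, truth = quiet_train
        short = [b for b in truth if b.end <= 40]
        audio, _ = ps.make_lung_audio(short, ps.LungAudioParams(), seed=2)
        x, fs = audio.values, audio.rate

        def rms(t0, t1):
            return np.sqrt(np.mean(x[int(t0 * fs):int(t1 * fs)] ** 2))

        insp = np.mean([rms(b.onset + 0.05, b.peak - 0.05) for b in short[2:8]])
        tail = rms(audio.duration - 1.5, audio.duration - 0.2)
        assert insp > 5 * tail

    def test_spectral_content_inside_band(self, quiet_train):
        _, _, truth = quiet_train
        short = [b for b in truth if b.end <= 30]
        audio, _ = ps.make_lung_audio(short, ps.LungAudioParams(n_crackles=4),
                                      seed=3)
        f, pxx = sps.periodogram(audio.values, audio.rate)
        inband = pxx[(f >= 100) & (f <= 1000)].sum() / pxx.sum()
        assert inband >= 0.95

    def test_generator_deterministic(self, quiet_train):
        _, _, truth = quiet_train
        short = [b for b in truth if b.end <= 20]
        a1, e1 = ps.make_lung_audio(short, ps.LungAudioParams(n_crackles=3), seed=4)
        a2, e2 = ps.make_lung_audio(short, ps.LungAudioParams(n_crackles=3), seed=4)
        assert np.array_equal(a1.values, a2.values)
        assert [(e.kind, e.time) for e in e1] == [(e.kind, e.time) for e in e2]


class TestCorruptSegment:
    def test_flatline_has_zero_variance(self, quiet_train):
        _, series, _ = quiet_train
        out = ps.corrupt_segment(series, (50.0, 70.0), "flatline", seed=0)
        i0, i1 = int(50 * series.rate), int(70 * series.rate)
        assert np.ptp(out.values[i0:i1]) == 0.0

    @pytest.mark.parametrize("mode", ["white-noise", "flatline", "spike-train"])
    def test_outside_interval_bit_identical(self, quiet_train, mode):
        _, series, _ = quiet_train
        out = ps.corrupt_segment(series, (50.0, 70.0), mode, seed=1)
        i0, i1 = int(50 * series.rate), int(70 * series.rate)
        assert np.array_equal(out.values[:i0], series.values[:i0])
        assert np.array_equal(out.values[i1:], series.values[i1:])

    def test_unknown_mode_rejected(self, quiet_train):
        _, series, _ = quiet_train
        with pytest.raises(ValueError, match="mode"):
            ps.corrupt_segment(series, (10.0, 20.0), "glitch", seed=0)

    def test_interval_must_lie_inside(self, quiet_train):
        _, series, _ = quiet_train
        with pytest.raises(ValueError):
            ps.corrupt_segment(series, (-5.0, 20.0), "flatline", seed=0)


class TestSessionSimulation:
    def test_session_carries_all_modalities(self, small_session):
        session, truth = small_session
        assert sorted(session.ip_channels) == [5, 50, 100, 150]
        assert len(session.bis_sweeps) == 30
        assert session.audio_channels
        assert truth.breaths and truth.cole is not None
        assert np.isfinite(truth.k_true)

    def test_channel_profile_scales_modulation(self, small_session):
        session, _ = small_session
        spans = {khz: np.ptp(ts.values) for khz, ts in session.ip_channels.items()}
        assert spans[100] > spans[5]  # 100 kHz carries the deepest modulation
        for khz, (offset, _) in _IP_CHANNEL_PROFILE.items():
            assert abs(session.ip_channels[khz].values.mean() - offset) < 3.0

    def test_study_structure_matches_protocol(self):
        study = ps.simulate_study(seed=3, duration_s=60.0)
        assert len(study) == 32
        tags = {}
        for session, _ in study:
            tags.setdefault(session.subject, []).append(session.tag)
        assert len(tags) == 14
        n_visits = sorted(len(v) for v in tags.values())
        assert n_visits == [1, 1, 1, 1, 2, 2, 3, 3, 3, 3, 3, 3, 3, 3]
        paired = [s for s, v in tags.items()
                  if "admission" in v and "discharge" in v]
        assert len(paired) == 8
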