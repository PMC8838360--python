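import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pulmosense as ps
from pulmosense.core import AnalysisConfig, TimeSeries
from pulmosense.resp import (build_breaths, detect_breath_onsets, fuse_onsets,
                             label_breaths, mad_flags, plausibility_filter,
                             preprocess_ip, reject_outliers_mad,
                             score_window_sqi, window_segments, Breath,
                             WindowLabel, extract_breath_features)


class TestPreprocess:
    def test_respiratory_tone_passes_at_unit_gain_zero_lag(self):
        fs, f0 = 16.0, 0.3
        t = np.arange(0, 120, 1 / fs)
        series = TimeSeries(np.sin(2 * np.pi * f0 * t), rate=fs)
        out = preprocess_ip(series)
        assert out.rate == 100.0
        mid = out.values[2000:-2000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)
        # zero phase: peak cross-correlation with an ideal tone at lag 0
        ref = np.sin(2 * np.pi * f0 * out.times())[2000:-2000]
        lags = np.arange(-200, 201)
        xc = [np.dot(mid[200:-200], ref[200 + l:len(ref) - 200 + l]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_baseline_drift_suppressed(self):
        fs = 16.0
        t = np.arange(0, 120, 1 / fs)
        series = TimeSeries(5.0 * np.sin(2 * np.pi * 0.02 * t), rate=fs)
        out = preprocess_ip(series)
        assert np.abs(out.values[1000:-1000]).max() <= 0.5

    def test_fast_interference_suppressed(self):
        fs = 16.0
        t = np.arange(0, 120, 1 / fs)
        series = TimeSeries(np.sin(2 * np.pi * 2.0 * t), rate=fs)
        out = preprocess_ip(series)
        # >= 20 dB attenuation at 2 Hz
        assert np.abs(out.values[1000:-1000]).max() <= 0.1

    def test_too_short_series_names_minimum(self):
        series = TimeSeries(np.random.default_rng(0).normal(size=16 * 20),
                            rate=16.0)
        with pytest.raises(ValueError, match="need >"):
            preprocess_ip(series)

    def test_constant_offset_removed(self, quiet_train):
        _, series, _ = quiet_train
        shifted = TimeSeries(series.values + 50.0, rate=series.rate)
        a = preprocess_ip(series)
        b = preprocess_ip(shifted)
        assert np.allclose(a.values, b.values, atol=1e-6)


class TestWindowing:
    def test_stride_is_5_2_seconds(self):
        series = TimeSeries(np.zeros(16 * 60), rate=16.0)
        wins = window_segments(series, 26.0, 0.8)
        assert wins[1][0] - wins[0][0] == pytest.approx(5.2)

    def test_sixty_second_series_gives_seven_windows(self):
        series = TimeSeries(np.zeros(16 * 60), rate=16.0)
        wins = window_segments(series, 26.0, 0.8)
        assert len(wins) == 7
        assert wins[0][0] == pytest.approx(0.0)
        assert wins[-1][0] == pytest.approx(31.2)
        assert all(b - a == pytest.approx(26.0) for a, b in wins)

    def test_zero_overlap_tiles_disjointly(self):
        series = TimeSeries(np.zeros(1000), rate=10.0)
        wins = window_segments(series, 10.0, 0.0)
        for (a1, b1), (a2, _) in zip(wins[:-1], wins[1:]):
            assert b1 == pytest.approx(a2)

    def test_short_series_single_window(self):
        series = TimeSeries(np.zeros(100), rate=10.0)
        wins = window_segments(series, 26.0, 0.8)
        assert wins == [(0.0, 10.0)]


class TestOnsetDetection:
    def test_sinusoid_troughs_recovered(self):
        fs = 100.0
        t = np.arange(0, 26, 1 / fs)
        w = TimeSeries(np.sin(2 * np.pi * 0.25 * t), rate=fs)
        onsets = detect_breath_onsets(w)
        expected = [3.0, 7.0, 11.0, 15.0, 19.0, 23.0]
        assert len(onsets) == 6
        assert np.allclose(onsets, expected, atol=0.1)

    def test_all_zero_window_yields_nothing(self):
        w = TimeSeries(np.zeros(2600), rate=100.0)
        assert len(detect_breath_onsets(w)) == 0

    def test_output_strictly_increasing(self, quiet_result):
        assert np.all(np.diff(quiet_result.onsets) > 0)


class TestFusion:
    def test_idempotent_on_single_list(self):
        lst = [1.0, 3.5, 7.0]
        assert np.allclose(fuse_onsets([lst, lst], 0.25), lst)

    def test_offset_lists_merge_at_midpoints(self):
        a = [10.0, 20.0, 30.0]
        b = [10.1, 20.1, 30.1]
        fused = fuse_onsets([a, b], tolerance=0.25)
        assert np.allclose(fused, [10.05, 20.05, 30.05])

    def test_disjoint_lists_union(self):
        a, b = [1.0, 5.0], [3.0, 8.0]
        assert np.allclose(fuse_onsets([a, b], 0.25), [1.0, 3.0, 5.0, 8.0])

    def test_matches_brute_force_clustering(self, rng):
        """Greedy mean-merge equals exhaustive transitive clustering."""
        for _ in range(50):
            pts = np.sort(rng.uniform(0, 30, rng.integers(2, 15)))
            tol = 0.4
            fused = fuse_onsets([pts], tol)
            # oracle: transitive closure of |a-b| <= tol chains on sorted pts
            groups, cur = [], [pts[0]]
            for p in pts[1:]:
                if p - np.mean(cur) <= tol:
                    cur.append(p)
                else:
                    groups.append(cur)
                    cur = [p]
            groups.append(cur)
            oracle = [np.mean(g) for g in groups]
            # re-merge oracle means until stable, as the contract requires
            changed = True
            while changed:
                changed = False
                out = []
                for m in oracle:
                    if out and m - out[-1] <= tol:
                        out[-1] = (out[-1] + m) / 2
                        changed = True
                    else:
                        out.append(m)
                oracle = out
            assert len(fused) == len(oracle)
            assert np.allclose(fused, oracle, atol=tol)
            assert np.all(np.diff(fused) > tol)


def _uniform_breaths(n=5, ibi=3.0, start=1.0):
    return [Breath(onset=start + i * ibi, peak=start + i * ibi + 1.2,
                   end=start + (i + 1) * ibi) for i in range(n)]


class TestSQI:
    def test_identical_breaths_score_perfectly(self):
        fs = 100.0
        t = np.arange(0, 26, 1 / fs)
        w = TimeSeries(np.sin(2 * np.pi * t / 3.0 - np.pi / 2) + 1, rate=fs)
        breaths = [Breath(onset=3 * i, peak=3 * i + 1.5, end=3 * (i + 1))
                   for i in range(1, 6)]
        wl = score_window_sqi(w, breaths)
        assert wl.label == "good"
        assert wl.mean_template_corr == pytest.approx(1.0, abs=1e-6)
        assert wl.duration_cov == pytest.approx(0.0, abs=1e-12)

    def test_single_breath_window_is_bad(self):
        w = TimeSeries(np.sin(np.arange(0, 26, 0.01)), rate=100.0)
        wl = score_window_sqi(w, _uniform_breaths(n=1))
        assert wl.label == "bad"
        assert np.isnan(wl.mean_template_corr)
        assert np.isnan(wl.duration_cov)

    def test_corrupted_half_window_goes_bad(self, quiet_train):
        """Flat-lining half a window starves it of coherent member breaths."""
        params, series, _ = quiet_train
        corrupted = ps.corrupt_segment(series, (60.0, 120.0), "flatline", seed=0)
        res = ps.process_ip_channel(corrupted)
        inside = [wl for wl in res.window_labels
                  if wl.start >= 73.0 and wl.end <= 107.0]
        assert inside
        assert all(wl.label == "bad" for wl in inside)


class TestLabelFusion:
    def test_one_good_window_is_enough(self):
        breaths = _uniform_breaths(3)
        labels = [
            WindowLabel(0, 26, "bad", 0.5, 0.6, member_breaths=[0, 1, 2]),
            WindowLabel(5, 31, "good", 0.9, 0.1, member_breaths=[1]),
        ]
        flags = label_breaths(breaths, labels)
        assert flags == ["bad", "good", "bad"]

    def test_breath_in_no_window_stays_bad(self):
        breaths = _uniform_breaths(2)
        flags = label_breaths(breaths, [WindowLabel(0, 26, "good", 0.9, 0.1,
                                                    member_breaths=[0])])
        assert flags == ["good", "bad"]

    @given(st.lists(st.booleans(), min_size=1, max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_adding_good_window_never_demotes(self, window_goodness):
        """OR-fusion is monotone: extra good windows cannot flip good->bad."""
        breaths = _uniform_breaths(4)
        labels = [WindowLabel(0, 26, "good" if g else "bad", 0.9, 0.1,
                              member_breaths=[0, 1, 2, 3])
                  for g in window_goodness]
        before = list(label_breaths(breaths, labels))
        labels.append(WindowLabel(0, 26, "good", 0.95, 0.05,
                                  member_breaths=[0, 1, 2, 3]))
        after = label_breaths(breaths, labels)
        for b, a in zip(before, after):
            assert not (b == "good" and a == "bad")


class TestPlausibility:
    @pytest.mark.parametrize("ibi,kept", [
        (3.0, True),     # 20 bpm
        (20.0, False),   # 3 bpm, too slow
        (0.9, False),    # 66.7 bpm, too fast
        (15.0, True),    # 4 bpm boundary
        (1.0, True),     # 60 bpm boundary
    ])
    def test_rr_bounds(self, ibi, kept):
        b = Breath(onset=0.0, peak=0.4 * ibi, end=ibi)
        out = plausibility_filter([b])
        assert (len(out) == 1) == kept


class TestFeatures:
    def test_timing_additivity_and_rr(self, quiet_result):
        feats = quiet_result.features
        assert len(feats) > 50
        assert np.allclose(feats.ti + feats.te, feats.ibi, atol=1e-9)
        assert np.allclose(feats.rr, 60.0 / feats.ibi, atol=1e-9)
        assert np.allclose(feats.te_ti, feats.te / feats.ti, atol=1e-9)

    def test_symmetric_breaths_have_unit_te_ti(self):
        params = ps.BreathTrainParams(duration_s=300.0, rr_mean_bpm=20.0,
                                      ti_te_ratio=1.0, noise_sd_ohm=0.05,
                                      seed=5)
        series, _ = ps.make_breath_train(params)
        res = ps.process_ip_channel(series)
        assert res.summary.feature_mean["te_ti"] == pytest.approx(1.0, abs=0.05)

    def test_patient_regime_rr(self):
        # an inter-breath interval of 2.6 s corresponds to ~23.1 bpm
        assert 60.0 / 2.6 == pytest.approx(23.08, abs=0.01)

    def test_amplitudes_positive_for_clean_breaths(self, quiet_result):
        assert (quiet_result.retained.rpki > 0).all()
        assert (quiet_result.retained.rpke > 0).all()


class TestMADRejection:
    def test_worked_example(self):
        rr = np.array([10.0, 11.0, 10.0, 12.0, 11.0, 50.0])
        flags = mad_flags(rr, multiplier=4.0)
        assert list(flags) == [False, False, False, False, False, True]

    def test_all_equal_column_flags_nothing(self):
        assert not mad_flags(np.full(10, 3.3), 4.0).any()

    def test_union_fusion_removes_row_flagged_in_one_column(self):
        df = pd.DataFrame({
            "rr": [20.0, 20, 20, 20, 20, 20],
            "ti": [1.0, 1, 1, 1, 1, 1],
            "te": [1.5, 1.5, 1.4, 1.6, 1.5, 9.0],
            "te_ti": [1.0, 1, 1, 1, 1, 1],
            "rpki": [2.0, 2, 2, 2, 2, 2],
            "rpke": [2.0, 2, 2, 2, 2, 2],
        })
        retained, flagged = reject_outliers_mad(df)
        assert flagged.sum() == 1 and flagged[5]
        assert len(retained) == 5

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            reject_outliers_mad(pd.DataFrame(columns=["rr"]), columns=["rr"])

    @given(st.lists(st.floats(min_value=-50, max_value=50,
                              allow_nan=False, allow_infinity=False),
                    min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, values):
        """MAD flags equal the direct definition on arbitrary small samples."""
        x = np.asarray(values)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        expected = [abs(v - med) > 4 * mad if mad > 0 else False for v in x]
        assert list(mad_flags(x, 4.0)) == expected


class TestEndToEnd:
    @pytest.mark.parametrize("rr", [8, 20, 40])
    def test_noiseless_recovery(self, rr):
        """Mean RR/Ti/Te recovered within 1 bpm / 0.1 s / 0.1 s."""
        params = ps.BreathTrainParams(duration_s=300.0, rr_mean_bpm=float(rr),
                                      noise_sd_ohm=1e-9, seed=rr)
        series, truth = ps.make_breath_train(params)
        res = ps.process_ip_channel(series)
        rr_true = 60.0 / np.mean([b.end - b.onset for b in truth])
        ti_true = np.mean([b.peak - b.onset for b in truth])
        te_true = np.mean([b.end - b.peak for b in truth])
        assert abs(res.summary.feature_mean["rr"] - rr_true) < 1.0
        assert abs(res.summary.feature_mean["ti"] - ti_true) < 0.1
        assert abs(res.summary.feature_mean["te"] - te_true) < 0.1

    def test_retained_rr_within_plausibility_bounds(self, quiet_result):
        assert ((quiet_result.retained.rr >= 4.0)
                & (quiet_result.retained.rr <= 60.0)).all()

    def test_summary_counts_nested(self, quiet_result):
        s = quiet_result.summary
        assert (s.n_breaths_after_outlier <= s.n_breaths_good
                <= s.n_breaths_detected)

    def test_no_accepted_breath_inside_apnea(self, csr_signal):
        csr, mod, _ = csr_signal
        res = ps.process_ip_channel(mod)
        T = csr.cycle_length_s
        a = csr.apnea_fraction * T
        accepted = [b for b in res.breaths if b.quality == "good"
                    and 4 <= 60 / b.ibi <= 60]
        assert len(accepted) > 20
        for b in accepted:
            phi = b.onset % T
            interior = (phi < a / 2 - 0.3) or (phi > T - a / 2 + 0.3)
            assert not interior, f"accepted breath onset {b.onset} in apnea"
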