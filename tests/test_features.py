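import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emofuse as ef
from emofuse.exceptions import InsufficientDataError
from emofuse.features import (ALL_FEATURES, ECG_FEATURES, ECG_FREQUENCY_FEATURES,
                              ECG_NONLINEAR_FEATURES, ECG_TIME_FEATURES,
                              EDA_FEATURES, RSP_FEATURES, approximate_entropy,
                              feature_domain, sample_entropy)
from emofuse.preprocess import BreathCycleSet, EdaDecomposition, NNIntervalSeries


def make_nn(values):
    vals = np.asarray(values, dtype=float)
    anchors = np.concatenate([[0.0], np.cumsum(vals)[:-1] / 1000.0])
    return NNIntervalSeries(vals, anchors)


nn_series = st.lists(st.floats(min_value=400, max_value=1500), min_size=12,
                     max_size=60).map(make_nn)


class TestRegistry:
    def test_domain_counts(self):
        assert len(ECG_TIME_FEATURES) == 14
        assert len(ECG_FREQUENCY_FEATURES) == 4
        assert len(ECG_NONLINEAR_FEATURES) == 29
        assert len(ECG_FEATURES) == 47
        assert len(EDA_FEATURES) == 4
        assert len(RSP_FEATURES) == 7
        assert len(ALL_FEATURES) == 58

    def test_every_name_has_a_domain(self):
        for name in ALL_FEATURES:
            assert feature_domain(name) in {"ecg-time", "ecg-frequency",
                                            "ecg-nonlinear", "eda", "rsp"}

    def test_unregistered_name_rejected(self):
        from emofuse.features import FeatureVector
        with pytest.raises(Exception):
            FeatureVector({"NotAFeature": 1.0})


class TestHrvTime:
    def test_constant_series(self):
        vals = ef.hrv_time(make_nn([800, 800, 800, 800]))
        assert vals["RMSSD"] == 0 and vals["SDNN"] == 0
        assert vals["pNN50"] == 0 and vals["MeanNN"] == 800

    def test_rmssd_hand_computed(self):
        vals = ef.hrv_time(make_nn([800, 810, 790, 805]))
        expected = math.sqrt((10**2 + 20**2 + 15**2) / 3)
        assert vals["RMSSD"] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(15.546, abs=1e-3)

    def test_pnn50_saturates_for_large_swings(self):
        vals = ef.hrv_time(make_nn([800, 860, 800, 860]))
        assert vals["pNN50"] == 100.0

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientDataError):
            ef.hrv_time(make_nn([800, 800, 800]))

    @settings(max_examples=25, deadline=None)
    @given(nn_series)
    def test_definition_identities(self, nn):
        vals = ef.hrv_time(nn)
        x = nn.intervals_ms
        assert vals["SDNN"] == pytest.approx(np.std(x, ddof=1))
        assert vals["CVNN"] == pytest.approx(vals["SDNN"] / vals["MeanNN"])
        assert vals["IQRNN"] >= 0 and vals["HTI"] >= 1


class TestHrvFrequency:
    def test_metronomic_series_has_no_hf_power(self):
        nn = make_nn([800.0] * 80)
        vals = ef.hrv_frequency(nn)
        assert vals["HF"] == pytest.approx(0.0, abs=1e-6)
        assert vals["LnHF"] == pytest.approx(np.log(1e-12))

    def test_quarter_hz_modulation_lands_in_hf_band(self):
        # 0.25 Hz sinusoidal tachogram modulation: HF captures >= 90% of power
        t, intervals = 0.0, []
        while t < 120:
            nn_val = 800 + 50 * np.sin(2 * np.pi * 0.25 * t)
            intervals.append(nn_val)
            t += nn_val / 1000.0
        vals = ef.hrv_frequency(make_nn(intervals))
        total = vals["HF"] / vals["HFn"]
        assert vals["HF"] / total >= 0.9

    @settings(max_examples=15, deadline=None)
    @given(st.lists(st.floats(min_value=500, max_value=1200), min_size=60,
                    max_size=120).map(make_nn))
    def test_hfn_bounded(self, nn):
        vals = ef.hrv_frequency(nn)
        assert 0.0 <= vals["HFn"] <= 1.0

    def test_short_span_rejected(self):
        with pytest.raises(InsufficientDataError):
            ef.hrv_frequency(make_nn([800] * 10))


def sampen_bruteforce(x, m, r):
    """Independent template-counting oracle for SampEn."""
    x = np.asarray(x, float)
    n = len(x)

    def count(mm):
        templates = [x[i:i + mm] for i in range(n - m)]
        c = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if np.max(np.abs(templates[i] - templates[j])) <= r:
                    c += 1
        return c

    b, a = count(m), count(m + 1)
    if b == 0:
        return 0.0
    if a == 0:
        return float("inf")
    return -math.log(a / b)


def apen_bruteforce(x, m, r):
    x = np.asarray(x, float)
    n = len(x)

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for ti in templates:
            c = sum(1 for tj in templates if np.max(np.abs(ti - tj)) <= r)
            total += math.log(c / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


class TestHrvNonlinear:
    @settings(max_examples=25, deadline=None)
    @given(nn_series)
    def test_sd1_equals_rmssd_over_sqrt2(self, nn):
        vals = ef.hrv_nonlinear(nn)
        d = np.diff(nn.intervals_ms)
        # SD1 uses the unbiased variance of successive differences
        assert vals["SD1"] == pytest.approx(np.sqrt(np.var(d, ddof=1) / 2), rel=1e-9)

    def test_alternating_series_is_fully_fragmented(self):
        vals = ef.hrv_nonlinear(make_nn([800, 850] * 8))
        assert vals["PIP"] == 100.0

    def test_ramp_sample_entropy_zero(self):
        x = np.arange(50) * 10.0 + 500.0  # constant-increment ramp
        r = 0.2 * np.std(x, ddof=1)
        assert sample_entropy(x, 2, r) == 0.0
        assert sampen_bruteforce(x, 2, r) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_entropies_match_bruteforce(self, seed):
        x = np.random.default_rng(seed).normal(800, 50, 50)
        r = 0.2 * np.std(x, ddof=1)
        assert sample_entropy(x, 2, r) == pytest.approx(sampen_bruteforce(x, 2, r), rel=1e-9)
        assert approximate_entropy(x, 2, r) == pytest.approx(apen_bruteforce(x, 2, r), rel=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(nn_series)
    def test_asymmetry_partitions_sum_to_one(self, nn):
        vals = ef.hrv_nonlinear(nn)
        d = np.diff(nn.intervals_ms)
        if np.any(d > 0) and np.any(d < 0):
            assert vals["C1d"] + vals["C1a"] == pytest.approx(1.0)
            assert vals["C2d"] + vals["C2a"] == pytest.approx(1.0)
            assert vals["Cd"] + vals["Ca"] == pytest.approx(1.0)
            assert 0 <= vals["GI"] <= 100 and 0 <= vals["PI"] <= 100

    def test_degenerate_constant_series_sentinels(self):
        vals = ef.hrv_nonlinear(make_nn([800.0] * 20))
        assert vals["SD1"] == 0 and vals["ApEn"] == 0 and vals["SampEn"] == 0
        assert np.isfinite(list(vals.values())).all()

    def test_poincare_area_identity(self):
        vals = ef.hrv_nonlinear(make_nn(np.random.default_rng(7).normal(800, 40, 60)))
        assert vals["S"] == pytest.approx(math.pi * vals["SD1"] * vals["SD2"], rel=1e-9)
        assert vals["CSI"] == pytest.approx(vals["SD2"] / vals["SD1"], rel=1e-9)


class TestEdaRspFeatures:
    def test_zero_event_decomposition(self):
        dec = EdaDecomposition(np.full(100, 2.0), np.zeros(100), [], 25)
        vals = ef.eda_features(dec, 60.0)
        assert vals["SCR_count_per_min"] == 0 and vals["SCR_mean_amplitude"] == 0
        assert vals["tonic_mean"] == pytest.approx(2.0)

    def test_scr_rate_recovered_from_simulation(self):
        rates = []
        for s in range(4):
            eda, _ = ef.simulate_eda(60, 25, 2.0, scr_rate_per_min=6, scr_amp_uS=0.5,
                                     seed=s)
            dec = ef.eda_decompose(eda, 25)
            rates.append(ef.eda_features(dec, 60.0)["SCR_count_per_min"])
        assert abs(np.mean(rates) - 6) <= 2

    def test_jitter_free_breathing_statistics(self):
        rsp, _ = ef.simulate_rsp(60, 25, 12, amp=1.0, amp_var=0.0, seed=0,
                                 period_jitter=0.0)
        vals, ok = ef.rsp_features(ef.segment_breaths(rsp, 25), 60.0)
        assert ok
        assert vals["breath_rate_mean"] == pytest.approx(12, rel=0.05)
        assert vals["amplitude_var"] == pytest.approx(0.0, abs=1e-3)
        assert vals["cycle_duration_mean"] == pytest.approx(5.0, rel=0.05)

    def test_amplitude_max_dominates_mean(self):
        rsp, _ = ef.simulate_rsp(60, 25, 14, amp=1.0, amp_var=0.3, seed=5)
        vals, _ok = ef.rsp_features(ef.segment_breaths(rsp, 25), 60.0)
        assert vals["amplitude_max"] >= vals["amplitude_mean"]

    def test_empty_cycle_set_flagged(self):
        vals, ok = ef.rsp_features(BreathCycleSet([]), 60.0)
        assert not ok and all(v == 0.0 for v in vals.values())


class TestExtractAll:
    def test_full_vector_contract(self, strong_trials):
        fv = ef.extract_all(strong_trials[1])
        assert len(fv) == 58
        assert list(fv.values.keys()) == list(ALL_FEATURES)
        ecg_names = [n for n in fv.values if feature_domain(n).startswith("ecg")]
        assert len(ecg_names) == 47

    def test_deterministic(self, strong_trials):
        a = ef.extract_all(strong_trials[1]).as_array()
        b = ef.extract_all(strong_trials[1]).as_array()
        assert np.array_equal(a, b)

    def test_hrv_features_invariant_to_time_shift(self):
        x = np.random.default_rng(3).normal(800, 40, 80)
        anchors = np.concatenate([[0.0], np.cumsum(x)[:-1] / 1000.0])
        nn0 = NNIntervalSeries(x, anchors)
        nn1 = NNIntervalSeries(x, anchors + 500.0)
        for f in (ef.hrv_time, ef.hrv_frequency, ef.hrv_nonlinear):
            v0, v1 = f(nn0), f(nn1)
            for k in v0:
                assert v0[k] == pytest.approx(v1[k], rel=1e-9, abs=1e-12)
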