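import numpy as np
import pandas as pd
import pytest

from e4stress import (
    FEATURE_COLUMNS,
    LabeledSegment,
    assemble_feature_table,
    prv_hf_power,
    prv_sd2,
    prv_time_features,
    scr_features,
    signal_statistics,
    zscore_standardize,
)
from e4stress.eda import SCREvent, SCREventList
from e4stress.features import (
    EDA_COLUMNS,
    PPG_COLUMNS,
    SCR_COLUMNS,
    apply_standardization,
)
from e4stress.ppg import PPSeries


def pp_series(intervals_ms):
    return PPSeries(
        peak_times_s=np.empty(0),
        pp_intervals_ms=np.asarray(intervals_ms, float),
        excluded_ms=np.empty(0),
    )


def seg(values, rate=64.0, label=0):
    return LabeledSegment(values=np.asarray(values, float), rate_hz=rate, label=label)


class TestPrvTimeFeatures:
    def test_constant_intervals(self):
        mean_pp, std_pp, m_hr, std_hr = prv_time_features(pp_series([1000, 1000, 1000]))
        assert (mean_pp, std_pp, m_hr, std_hr) == (1000, 0, 60, 0)

    def test_hand_computed_example(self):
        mean_pp, std_pp, m_hr, std_hr = prv_time_features(pp_series([800, 1000, 1200]))
        assert mean_pp == pytest.approx(1000)
        assert std_pp == pytest.approx(200)
        # HR series is 60000/PP per beat: (75, 60, 50)
        assert m_hr == pytest.approx(61.6667, abs=1e-3)
        assert std_hr == pytest.approx(np.std([75, 60, 50], ddof=1))

    def test_single_interval_maps_to_120_bpm(self):
        hr = 60000.0 / 500.0
        assert hr == pytest.approx(120)
        with pytest.raises(ValueError):
            prv_time_features(pp_series([500]))


class TestPrvHfPower:
    def _tachogram(self, freq_hz, amp_ms=50.0, total_s=120.0):
        # build PP series whose interval sequence carries a single tone
        intervals = []
        t = 0.0
        while t < total_s:
            pp = 1000.0 + amp_ms * np.sin(2 * np.pi * freq_hz * t)
            intervals.append(pp)
            t += pp / 1000.0
        return pp_series(intervals)

    def test_constant_tachogram_has_no_hf_power(self):
        assert prv_hf_power(pp_series([1000.0] * 60)) <= 1e-6

    def test_in_band_tone_dominates(self):
        pp = self._tachogram(0.25)
        hf = prv_hf_power(pp)
        total = prv_hf_power(pp, band=(0.0, 2.0))
        assert hf >= 0.8 * total

    def test_out_of_band_tone_excluded(self):
        pp = self._tachogram(0.05)
        hf = prv_hf_power(pp)
        total = prv_hf_power(pp, band=(0.0, 2.0))
        assert hf <= 0.1 * total

    def test_too_few_intervals(self):
        with pytest.raises(ValueError):
            prv_hf_power(pp_series([1000.0] * 5))


class TestPrvSd2:
    def test_constant_and_alternating_are_zero(self):
        assert prv_sd2(pp_series([900.0] * 10)) == 0
        # pure alternation: all successive sums equal 1600
        assert prv_sd2(pp_series([700, 900] * 5)) == pytest.approx(0)

    def test_hand_computed_example(self):
        # sums (1700, 1900, 2100), SD 200, SD2 = 200/sqrt(2)
        assert prv_sd2(pp_series([800, 900, 1000, 1100])) == pytest.approx(141.42, abs=0.01)

    def test_coefficient_is_configurable(self):
        assert prv_sd2(pp_series([800, 900, 1000, 1100]), coefficient=1.0) == pytest.approx(200)


class TestSignalStatistics:
    def test_constant_signal(self):
        stats = signal_statistics(seg(np.full(100, 4.2)), "BVP")
        for key in ("Mean_BVP", "Median_BVP", "Mode_BVP", "Min_BVP", "Max_BVP"):
            assert stats[key] == pytest.approx(4.2)
        for key in ("Std_BVP", "M_d1", "Std_d1", "M_d2", "Std_d2"):
            assert stats[key] == 0

    def test_even_n_median_and_mode(self):
        stats = signal_statistics(seg([1, 2, 2, 5]), "EDA")
        assert stats["Median_EDA"] == 2
        assert stats["Mode_EDA"] == 2
        assert stats["Mean_EDA"] == pytest.approx(2.5)

    def test_mode_tie_breaks_to_smallest(self):
        stats = signal_statistics(seg([1.0, 1.0, 3.0, 3.0, 2.0]), "EDA")
        assert stats["Mode_EDA"] == 1.0

    def test_ramp_first_difference(self):
        rate, slope = 64.0, 2.0
        t = np.arange(640) / rate
        stats = signal_statistics(seg(slope * t, rate), "BVP")
        # raw per-sample differences: slope / rate
        assert stats["M_d1"] == pytest.approx(slope / rate)
        assert stats["Std_d1"] == pytest.approx(0, abs=1e-12)
        assert stats["M_d2"] == pytest.approx(0, abs=1e-12)


class TestScrFeatures:
    def test_zero_fill_without_events(self):
        out = scr_features(SCREventList((), np.zeros(10)))
        assert out == {"M_D": 0, "M_Amp": 0, "M_RT": 0, "N_PEAKS": 0, "M_SCR": 0}

    def test_means_over_events(self):
        events = SCREventList(
            (
                SCREvent(1.0, 2.0, 0.3, 1.0, 5.0),
                SCREvent(10.0, 13.0, 0.5, 3.0, 8.0),
            ),
            phasic_trace=np.array([0.0, 0.5]),
        )
        out = scr_features(events)
        assert out["N_PEAKS"] == 2
        assert out["M_RT"] == pytest.approx(2.0)
        assert out["M_Amp"] == pytest.approx(0.4)
        assert out["M_D"] == pytest.approx(6.5)
        assert out["M_SCR"] == pytest.approx(0.25)


class TestAssembleFeatureTable:
    def test_clean_pipeline_table_shape(self, clean_pipeline_result):
        table = clean_pipeline_result.table
        assert list(table.columns[:27]) == list(FEATURE_COLUMNS)
        assert len(FEATURE_COLUMNS) == 27
        assert len(PPG_COLUMNS) == 16
        assert len(EDA_COLUMNS) == 6
        assert len(SCR_COLUMNS) == 5
        assert table[list(FEATURE_COLUMNS)].notna().all().all()
        assert set(table["label"]) == {0, 1}

    def test_sd_features_nonnegative_min_below_max(self, clean_pipeline_result):
        table = clean_pipeline_result.table
        for col in ("std_PP", "std_HR", "Std_BVP", "Std_EDA", "Std_d1", "Std_d2"):
            assert (table[col] >= 0).all()
        assert (table["Min_BVP"] <= table["Median_BVP"]).all()
        assert (table["Median_BVP"] <= table["Max_BVP"]).all()
        assert (table["Min_EDA"] <= table["Max_EDA"]).all()

    def test_stress_contrast_recovered(self, clean_pipeline_result):
        table = clean_pipeline_result.table
        means = table.groupby("label")[["M_HR", "N_PEAKS"]].mean()
        # generator: +15 bpm and higher SCR rate under stress
        assert means.loc[1, "M_HR"] - means.loc[0, "M_HR"] == pytest.approx(15, abs=3)
        assert means.loc[1, "N_PEAKS"] > means.loc[0, "N_PEAKS"]

    def test_mismatched_inputs_error(self):
        with pytest.raises(ValueError):
            assemble_feature_table([], [pp_series([800, 900])], [], [])


class TestZscoreStandardize:
    def test_fit_on_all_rows_gives_unit_columns(self, clean_pipeline_result):
        table = clean_pipeline_result.table
        std, params = zscore_standardize(table)
        scaled = [c for c in FEATURE_COLUMNS if c not in params.zero_variance]
        for c in scaled:
            assert std[c].mean() == pytest.approx(0, abs=1e-9)
            assert std[c].std(ddof=1) == pytest.approx(1, abs=1e-9)

    def test_small_column_example(self):
        table = pd.DataFrame({"Mean_PP": [1.0, 2.0, 3.0]})
        std, _ = zscore_standardize(table, columns=("Mean_PP",))
        np.testing.assert_allclose(std["Mean_PP"], [-1, 0, 1])

    def test_held_out_rows_use_training_parameters(self):
        table = pd.DataFrame({"Mean_PP": [1.0, 2.0, 3.0, 10.0]})
        fit_rows = np.array([True, True, True, False])
        std, params = zscore_standardize(table, fit_rows=fit_rows, columns=("Mean_PP",))
        assert std["Mean_PP"].iloc[3] == pytest.approx((10 - 2) / 1.0)
        held = apply_standardization(pd.DataFrame({"Mean_PP": [5.0]}), params)
        assert held["Mean_PP"].iloc[0] == pytest.approx(3.0)

    def test_zero_variance_column_flagged(self):
        table = pd.DataFrame({"Mean_PP": [1.0, 1.0, 1.0], "std_PP": [1.0, 2.0, 3.0]})
        std, params = zscore_standardize(table, columns=("Mean_PP", "std_PP"))
        assert params.zero_variance == ("Mean_PP",)
        np.testing.assert_allclose(std["Mean_PP"], 1.0)
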