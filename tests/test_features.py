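"""Featurizer contract: the five time-series summaries, the PAC threshold
rule, event frequencies, the 60-column table, and baseline encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_summaries

from emapredict.features import (
    build_feature_table,
    default_pac_threshold,
    encode_baseline,
    event_frequencies,
    feature_columns,
    fit_pac_thresholds,
    series_summaries,
)
from emapredict.io import EmaDataset, day_aggregate
from emapredict.schema import DAILY_SERIES_VARS


class TestSeriesSummaries:
    def test_constant_series(self):
        s = series_summaries([3, 3, 3, 3], [1, 2, 3, 4], pac_threshold=2)
        assert s == (3.0, 0.0, 0.0, 0.0, 0.0)

    def test_exact_line_slope(self):
        s = series_summaries([1, 2, 3], [1, 2, 3], pac_threshold=1)
        assert s.slope == pytest.approx(1.0)

    def test_alternating_extremes_against_oracle(self):
        values, days = [0, 6, 0, 6], [1, 2, 3, 4]
        s = series_summaries(values, days, pac_threshold=3)
        assert s.max_change == 6.0
        assert s.pac == 1.0  # all 3 jumps are >= 3
        ref = brute_summaries(values, days, 3)
        assert s.sd == pytest.approx(ref["sd"], rel=1e-12)
        assert s.slope == pytest.approx(ref["slope"], rel=1e-12)

    def test_gap_preserving_slope_uses_day_index(self):
        # days 1,2,10: slope must reflect the calendar gap, not ranks
        s = series_summaries([0.0, 1.0, 9.0], [1, 2, 10], pac_threshold=1)
        ref = brute_summaries([0.0, 1.0, 9.0], [1, 2, 10], 1)
        assert s.slope == pytest.approx(ref["slope"], rel=1e-12)
        assert s.slope != pytest.approx(np.polyfit([0, 1, 2], [0, 1, 9], 1)[0])

    def test_single_observation_policy(self):
        s = series_summaries([4.0], [7], pac_threshold=1)
        assert s == (4.0, 0.0, 0.0, 0.0, 0.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            series_summaries([], [], pac_threshold=1)

    def test_oracle_equivalence_random_series(self):
        """1000 random series agree with the brute-force oracle to 1e-10."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 26))
            days = np.sort(rng.choice(np.arange(1, 26), size=n, replace=False))
            values = rng.normal(3, 2, size=n)
            thr = float(rng.uniform(0.2, 3.0))
            s = series_summaries(values, days, thr)
            ref = brute_summaries(list(values), list(days), thr)
            for name in ("mean", "sd", "slope", "max_change", "pac"):
                assert getattr(s, name) == pytest.approx(
                    ref[name], rel=1e-10, abs=1e-10)

    @given(
        values=st.lists(st.floats(0, 6, allow_nan=False), min_size=3, max_size=20),
        shift=st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=60, derandomize=True)
    def test_shift_invariance(self, values, shift):
        """Adding a constant leaves sd, slope, max_change and pac unchanged
        and shifts the mean by exactly that constant."""
        days = list(range(1, len(values) + 1))
        a = series_summaries(values, days, pac_threshold=1.0)
        b = series_summaries([v + shift for v in values], days, pac_threshold=1.0)
        assert b.mean == pytest.approx(a.mean + shift, abs=1e-9)
        assert b.sd == pytest.approx(a.sd, abs=1e-9)
        assert b.slope == pytest.approx(a.slope, abs=1e-9)
        assert b.max_change == pytest.approx(a.max_change, abs=1e-9)
        assert b.pac == a.pac


class TestPacThreshold:
    def test_constant_differences(self):
        assert default_pac_threshold([[0, 2, 4, 6]]) == pytest.approx(2.0)

    def test_linear_interpolation_percentile(self):
        # pooled |diffs| = 0..10 -> 90th percentile 9.0
        series = [np.cumsum([0] + list(range(11)))]
        assert default_pac_threshold(series) == pytest.approx(9.0)

    def test_single_pair(self):
        assert default_pac_threshold([[1.0, 4.5]]) == pytest.approx(3.5)

    def test_no_differences_raises(self):
        with pytest.raises(ValueError):
            default_pac_threshold([[1.0], [2.0]])

    def test_fit_on_daily_matches_pooled_definition(self, small_daily):
        thresholds = fit_pac_thresholds(small_daily)
        var = "event_count"
        pooled = []
        for _, sub in small_daily.sort_values("day").groupby("participant_id"):
            pooled.extend(np.abs(np.diff(sub[var].to_numpy())))
        assert thresholds[var] == pytest.approx(np.percentile(pooled, 90))


class TestEventFrequencies:
    def _daily(self, rows):
        from emapredict.io import day_aggregate
        df = pd.DataFrame(rows)
        return day_aggregate(EmaDataset(df))

    def test_no_events_all_zero(self, complete_cohort):
        _, surveys, _, _ = complete_cohort
        pid = surveys["participant_id"].iloc[0]
        quiet = surveys.copy()
        quiet.loc[quiet["participant_id"] == pid,
                  ["events", "most_stressful"]] = ""
        quiet.loc[quiet["participant_id"] == pid, "worry"] = pd.NA
        daily = day_aggregate(EmaDataset(quiet))
        counts = event_frequencies(daily, pid)
        assert all(v == 0 for v in counts.values())

    def test_direct_count_with_window(self):
        """Marriage endorsed on 5 retained days, most-stressful on 2 of them;
        days outside the window are ignored."""
        rows = []
        for day in range(1, 8):
            endorsed = day <= 5
            most = "marriage" if day <= 2 else ("economy" if endorsed else "")
            events = ("marriage;economy" if endorsed else "")
            for slot in ("morning", "evening"):
                row = {"participant_id": "p1", "day": day, "slot": slot,
                       "events": events, "most_stressful": most,
                       "worry": 3 if endorsed else pd.NA}
                for item in DAILY_SERIES_VARS[:6]:
                    row[item] = 3
                rows.append(row)
        daily = day_aggregate(EmaDataset(pd.DataFrame(rows)))
        counts = event_frequencies(daily, "p1")
        assert counts["freq_marriage"] == 5
        assert counts["freq_ms_marriage"] == 2
        windowed = event_frequencies(daily, "p1", window=range(1, 4))
        assert windowed["freq_marriage"] == 3
        assert windowed["freq_ms_marriage"] == 2


class TestFeatureTable:
    def test_exactly_60_columns_any_window(self, small_daily, small_cohort):
        _, _, baselines, _ = small_cohort
        pids = sorted(baselines["participant_id"])
        for window in (None, range(9, 18), range(1, 2), range(1, 12)):
            table = build_feature_table(small_daily, window, participants=pids)
            assert table.shape == (len(pids), 60)
            assert list(table.columns) == feature_columns()
            assert not table.isna().any().any()

    def test_wave_window_restricts_days(self, small_daily):
        wave2 = build_feature_table(small_daily, window=range(9, 18))
        manual = small_daily[small_daily["day"].between(9, 17)]
        pid = manual["participant_id"].iloc[0]
        sub = manual[manual["participant_id"] == pid]
        assert wave2.loc[pid, "event_count_mean"] == pytest.approx(
            sub["event_count"].mean())

    def test_first_day_window_degenerates_to_policy(self, small_daily):
        k1 = build_feature_table(small_daily, window=range(1, 2))
        for var in DAILY_SERIES_VARS:
            for s in ("sd", "slope", "max_change", "pac"):
                assert (k1[f"{var}_{s}"] == 0).all()

    def test_matches_scalar_reference_per_participant(self, small_daily):
        thresholds = fit_pac_thresholds(small_daily)
        table = build_feature_table(small_daily, pac_thresholds=thresholds)
        rng = np.random.default_rng(0)
        pids = rng.choice(table.index, size=5, replace=False)
        for pid in pids:
            sub = small_daily[small_daily["participant_id"] == pid].sort_values("day")
            for var in DAILY_SERIES_VARS:
                ref = series_summaries(sub[var].to_numpy(), sub["day"].to_numpy(),
                                       thresholds[var])
                for s in ("mean", "sd", "slope", "max_change", "pac"):
                    assert table.loc[pid, f"{var}_{s}"] == pytest.approx(
                        getattr(ref, s), rel=1e-10, abs=1e-10), (pid, var, s)
            freqs = event_frequencies(small_daily, pid)
            for name, val in freqs.items():
                assert table.loc[pid, name] == val

    def test_permuting_input_rows_permutes_nothing(self, small_daily):
        a = build_feature_table(small_daily)
        shuffled = small_daily.sample(frac=1.0, random_state=4)
        b = build_feature_table(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_participant_without_days_gets_policy_row(self, small_daily, caplog):
        import logging
        pids = sorted(small_daily["participant_id"].unique()) + ["ghost"]
        with caplog.at_level(logging.WARNING):
            table = build_feature_table(small_daily, participants=pids)
        assert table.shape[0] == len(pids)
        assert (table.loc["ghost"] == 0).all()
        assert "no retained day" in caplog.text


class TestEncodeBaseline:
    def test_all_negative_history_is_zero_row(self):
        df = pd.DataFrame([{
            "participant_id": "p1", "baseline_si": 0, "nssi_freq_band": "0",
            "lifetime_attempt": 0, "psych_dx_history": 0, "psych_tx_history": 0,
            "family_attempt_history": 0, "family_dx_history": 0,
        }])
        enc = encode_baseline(df)
        assert enc.shape == (1, 7)
        assert (enc.loc["p1"] == 0).all()

    @pytest.mark.parametrize("band, code", [("0", 0), ("1-10", 1),
                                            ("11-50", 2), (">=51", 3)])
    def test_nssi_codebook(self, band, code):
        df = pd.DataFrame([{
            "participant_id": "p1", "baseline_si": 1, "nssi_freq_band": band,
            "lifetime_attempt": 0, "psych_dx_history": 1, "psych_tx_history": 0,
            "family_attempt_history": 0, "family_dx_history": 1,
        }])
        assert encode_baseline(df).loc["p1", "nssi_freq_band"] == code

    def test_unknown_band_rejected(self):
        df = pd.DataFrame([{
            "participant_id": "p1", "baseline_si": 0, "nssi_freq_band": "lots",
            "lifetime_attempt": 0, "psych_dx_history": 0, "psych_tx_history": 0,
            "family_attempt_history": 0, "family_dx_history": 0,
        }])
        with pytest.raises(ValueError, match="lots"):
            encode_baseline(df)

    def test_duplicate_participant_rejected(self, small_cohort):
        _, _, baselines, _ = small_cohort
        dup = pd.concat([baselines, baselines.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            encode_baseline(dup)
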