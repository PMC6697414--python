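"""Evoked responses, responsiveness classification, receptive fields, BW/eBW."""

import numpy as np
import pandas as pd
import pytest

import whiskermap as wm
from conftest import make_trial_table


def _dff_matrix(mat, frame_rate=30.0):
    return wm.DffMatrix(
        dff={"m0": np.atleast_2d(mat)},
        f0={"m0": np.array([1.0])},
        frame_rate_hz=frame_rate,
        roi_ids=np.array(["r0"]),
    )


def _stim(onsets, whiskers):
    return pd.DataFrame(
        {
            "trial_id": range(len(onsets)),
            "movie_id": "m0",
            "onset_frame": onsets,
            "whisker": whiskers,
        }
    )


class TestEvokedResponse:
    windows = wm.AnalysisWindows(n_perm=300)

    def test_step_response(self):
        trace = np.zeros(120)
        trace[30:60] = 0.5  # evoked window frames all 0.5, baseline 0
        out = wm.evoked_response_per_trial(
            _dff_matrix(trace), _stim([30], ["D2"]), self.windows
        )
        assert out["evoked_dff"].iloc[0] == pytest.approx(0.5)

    def test_constant_trace_zero(self):
        out = wm.evoked_response_per_trial(
            _dff_matrix(np.full(120, 0.3)), _stim([30], ["D2"]), self.windows
        )
        assert out["evoked_dff"].iloc[0] == pytest.approx(0.0)

    def test_sign_convention(self):
        trace = np.zeros(120)
        trace[15:30] = 0.2  # baseline
        trace[30:60] = 0.1  # evoked
        out = wm.evoked_response_per_trial(
            _dff_matrix(trace), _stim([30], ["D2"]), self.windows
        )
        assert out["evoked_dff"].iloc[0] == pytest.approx(-0.1)

    def test_out_of_range_trial_listed(self):
        with pytest.raises(ValueError, match=r"trial_ids: \[0\]"):
            wm.evoked_response_per_trial(
                _dff_matrix(np.zeros(100)), _stim([95], ["D2"]), self.windows
            )


class TestClassifyResponsive:
    windows = wm.AnalysisWindows(n_perm=500)

    def test_strong_effect_detected_and_null_not(self):
        rng = np.random.default_rng(0)
        data = {wk: rng.normal(0, 1, 30) for wk in wm.WHISKERS}
        data["D2"] = rng.normal(3, 1, 30)  # 3-SD effect
        data["BLANK"] = rng.normal(0, 1, 30)
        trials = make_trial_table(data)
        out = wm.classify_responsive(trials, self.windows, seed=1)
        assert bool(out["resp_D2"].iloc[0])
        assert bool(out["is_responsive"].iloc[0])

    def test_zero_variance_equal_groups_not_responsive(self):
        data = {wk: np.full(10, 0.2) for wk in list(wm.WHISKERS) + ["BLANK"]}
        out = wm.classify_responsive(make_trial_table(data), self.windows)
        assert not out["is_responsive"].iloc[0]
        assert (out[[f"p_{wk}" for wk in wm.WHISKERS]].iloc[0] == 1.0).all()

    def test_too_few_blanks_error(self):
        data = {wk: np.arange(10.0) for wk in wm.WHISKERS}
        data["BLANK"] = np.array([0.0, 1.0])
        with pytest.raises(ValueError, match="blank"):
            wm.classify_responsive(make_trial_table(data), self.windows)


class TestReceptiveField:
    def test_z_score_formula(self):
        rng = np.random.default_rng(4)
        blank = rng.normal(0.1, 0.2, 4000)
        data = {wk: np.full(5, 0.5) for wk in wm.WHISKERS}
        data["BLANK"] = blank
        rf = wm.receptive_field(make_trial_table(data))
        expected = (0.5 - blank.mean()) / blank.std(ddof=1)
        assert rf["z_D2"].iloc[0] == pytest.approx(expected)
        assert expected == pytest.approx(2.0, abs=0.1)
        assert rf["spontaneous"].iloc[0] == pytest.approx(np.median(blank))

    def test_whisker_at_blank_mean_zero_z(self):
        blank = np.array([0.0, 0.2, 0.4, 0.2, 0.2])
        data = {wk: np.full(3, blank.mean()) for wk in wm.WHISKERS}
        data["BLANK"] = blank
        rf = wm.receptive_field(make_trial_table(data))
        assert rf["z_C1"].iloc[0] == pytest.approx(0.0)

    def test_median_robust_to_outlier(self):
        base = {wk: np.array([1.0, 1.0, 1.0]) for wk in wm.WHISKERS}
        base["BLANK"] = np.array([0.0, 0.1, 0.2])
        rf1 = wm.receptive_field(make_trial_table(base))
        spiked = dict(base)
        spiked["D1"] = np.array([1.0, 1.0, 1.0, 1000.0])
        rf2 = wm.receptive_field(make_trial_table(spiked))
        assert rf2["median_D1"].iloc[0] == rf1["median_D1"].iloc[0]

    def test_zero_blank_sd_warns_nan(self):
        data = {wk: np.arange(3.0) for wk in wm.WHISKERS}
        data["BLANK"] = np.full(5, 0.1)
        with pytest.warns(UserWarning, match="blank SD"):
            rf = wm.receptive_field(make_trial_table(data))
        assert np.isnan(rf["z_D2"].iloc[0])


class TestBestAndEqualBest:
    windows = wm.AnalysisWindows(n_perm=500)

    def test_exact_tie_smallest_label_both_in_ebw(self):
        rng = np.random.default_rng(1)
        data = {wk: rng.normal(0, 0.1, 20) for wk in wm.WHISKERS}
        tied = rng.normal(2.0, 0.1, 20)
        data["D3"] = tied
        data["C2"] = tied.copy()  # exact tie with a lexicographically smaller label
        data["BLANK"] = rng.normal(0, 0.1, 20)
        trials = make_trial_table(data)
        rf = wm.receptive_field(trials)
        out = wm.best_and_equal_best(trials, rf, self.windows, seed=0)
        assert out["bw"].iloc[0] == "C2"
        assert {"C2", "D3"} <= out["ebw_set"].iloc[0]

    def test_high_contrast_singleton(self):
        rng = np.random.default_rng(2)
        data = {wk: rng.normal(0.2, 0.1, 40) for wk in wm.WHISKERS}
        data["D2"] = rng.normal(1.0, 0.1, 40)
        data["BLANK"] = rng.normal(0, 0.1, 40)
        trials = make_trial_table(data)
        rf = wm.receptive_field(trials)
        out = wm.best_and_equal_best(trials, rf, self.windows, seed=0)
        assert out["bw"].iloc[0] == "D2"
        assert out["ebw_set"].iloc[0] == frozenset({"D2"})

    def test_flat_tuning_keeps_most_whiskers(self):
        rng = np.random.default_rng(3)
        data = {wk: rng.normal(0.5, 0.2, 40) for wk in wm.WHISKERS}
        data["BLANK"] = rng.normal(0, 0.2, 40)
        trials = make_trial_table(data)
        rf = wm.receptive_field(trials)
        out = wm.best_and_equal_best(trials, rf, self.windows, seed=0)
        assert len(out["ebw_set"].iloc[0]) >= 8


class TestRankOrderedRf:
    def test_single_roi_sorted_vector(self):
        rng = np.random.default_rng(5)
        data = {wk: rng.normal(size=6) for wk in wm.WHISKERS}
        data["BLANK"] = rng.normal(size=20)
        rf = wm.receptive_field(make_trial_table(data))
        out = wm.rank_ordered_rf(rf)
        z = rf[[f"z_{wk}" for wk in wm.WHISKERS]].iloc[0].to_numpy()
        np.testing.assert_allclose(out, np.sort(z)[::-1])
        assert (np.diff(out) <= 1e-12).all()

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(6)
        vals = {wk: rng.normal(size=6) for wk in wm.WHISKERS}
        blank = rng.normal(size=20)
        rf1 = wm.receptive_field(make_trial_table({**vals, "BLANK": blank}))
        shuffled_labels = list(wm.WHISKERS)[::-1]
        vals2 = dict(zip(shuffled_labels, vals.values()))
        rf2 = wm.receptive_field(make_trial_table({**vals2, "BLANK": blank}))
        np.testing.assert_allclose(wm.rank_ordered_rf(rf1), wm.rank_ordered_rf(rf2))


class TestCwSwProfile:
    @staticmethod
    def _rf_for(columns):
        rng = np.random.default_rng(7)
        frames = []
        for i, col in enumerate(columns):
            data = {wk: rng.normal(size=5) for wk in wm.WHISKERS}
            data["BLANK"] = rng.normal(size=10)
            frames.append(make_trial_table(data, roi_id=f"r{i}", start_trial=100 * i))
        rf = wm.receptive_field(pd.concat(frames, ignore_index=True))
        assignment = pd.DataFrame(
            {"roi_id": [f"r{i}" for i in range(len(columns))], "column": columns}
        )
        return rf, assignment

    def test_d2_neighbors(self):
        rf, assignment = self._rf_for(["D2"] * 3)
        per_roi, agg = wm.cw_sw_profile(rf, assignment)
        row = per_roi.iloc[0]
        src = rf.iloc[0]
        assert row["cw"] == src["z_D2"]
        assert row["within_arc_minus_row"] == src["z_C2"]
        assert row["within_arc_plus_row"] == src["z_E2"]
        assert row["within_row_minus_arc"] == src["z_D1"]
        assert row["within_row_plus_arc"] == src["z_D3"]

    def test_grid_edge_missing(self):
        rf, assignment = self._rf_for(["C1"] * 3)
        per_roi, _ = wm.cw_sw_profile(rf, assignment)
        assert np.isnan(per_roi["within_arc_minus_row"].iloc[0])
        assert np.isnan(per_roi["within_row_minus_arc"].iloc[0])

    def test_small_columns_excluded_from_aggregate(self):
        rf, assignment = self._rf_for(["D2", "D2", "D2", "E3"])
        _, agg = wm.cw_sw_profile(rf, assignment, min_rois_per_column=3)
        assert agg.loc[agg["position"] == "cw", "n"].iloc[0] == 3
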