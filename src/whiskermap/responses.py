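"""Trial-level evoked responses, responsiveness, and receptive-field tuning.

The evoked response of an ROI on a trial is the mean dF/F in the 1 s
window after train onset minus the mean dF/F in the 0.5 s before onset.
An ROI counts as responsive to a whisker if its evoked responses exceed
the blank-trial responses by a one-sided permutation test, with
Benjamini-Hochberg correction across the nine whiskers per ROI; an ROI is
whisker-responsive if it is responsive to at least one whisker.

Receptive fields are summarized by the per-whisker median evoked dF/F and
its z-score against the blank-trial distribution.  The best whisker (BW)
evokes the largest mean dF/F; the equal-best set (eBW) additionally
contains every whisker whose mean response is statistically
indistinguishable from the BW (one-sided BW-vs-whisker permutation tests,
BH-corrected across the eight comparisons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import BLANK, WHISKERS, row_arc
from .stats import fdr_bh, permutation_mean_test


@dataclass
class AnalysisWindows:
    """Evoked/baseline windows (s, half-open, relative to train onset)."""

    evoked_window_s: tuple[float, float] = (0.0, 1.0)
    baseline_window_s: tuple[float, float] = (-0.5, 0.0)
    alpha: float = 0.05
    n_perm: int = 10000

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        e0, e1 = self.evoked_window_s
        b0, b1 = self.baseline_window_s
        if not (e0 < e1 and b0 < b1):
            raise ValueError("windows must be non-empty")
        if max(b0, e0) < min(b1, e1):
            raise ValueError("evoked and baseline windows overlap")

    def frames(self, frame_rate_hz: float) -> tuple[int, int, int, int]:
        """(evoked_start, evoked_stop, baseline_start, baseline_stop) frame offsets."""
        e0, e1 = self.evoked_window_s
        b0, b1 = self.baseline_window_s
        r = frame_rate_hz
        return (
            int(round(e0 * r)),
            int(round(e1 * r)),
            int(round(b0 * r)),
            int(round(b1 * r)),
        )


def evoked_response_per_trial(dff, stimulus: pd.DataFrame, windows: AnalysisWindows):
    """Per-ROI, per-trial evoked dF/F (evoked-window mean minus baseline mean).

    ``dff`` is a :class:`~whiskermap.preprocess.DffMatrix`.  Returns a long
    DataFrame with columns roi_id, trial_id, whisker, evoked_dff.
    """
    windows.validate()
    e0, e1, b0, b1 = windows.frames(dff.frame_rate_hz)
    roi_ids = dff.roi_ids
    bad_trials = []
    frames = {mid: mat.shape[1] for mid, mat in dff.dff.items()}
    for _, row in stimulus.iterrows():
        mid = row["movie_id"]
        onset = int(row["onset_frame"])
        if mid not in frames or onset + b0 < 0 or onset + e1 > frames[mid]:
            bad_trials.append(row["trial_id"])
    if bad_trials:
        raise ValueError(f"trial windows out of range for trial_ids: {bad_trials}")

    chunks = []
    for mid, mat in dff.dff.items():
        sub = stimulus[stimulus["movie_id"] == mid]
        if sub.empty:
            continue
        onsets = sub["onset_frame"].to_numpy(dtype=int)
        ev = np.stack([mat[:, o + e0 : o + e1].mean(axis=1) for o in onsets], axis=1)
        base = np.stack([mat[:, o + b0 : o + b1].mean(axis=1) for o in onsets], axis=1)
        resp = ev - base  # (n_rois, n_trials_in_movie)
        chunks.append(
            pd.DataFrame(
                {
                    "roi_id": np.repeat(roi_ids, len(sub)),
                    "trial_id": np.tile(sub["trial_id"].to_numpy(), len(roi_ids)),
                    "whisker": np.tile(sub["whisker"].to_numpy(), len(roi_ids)),
                    "evoked_dff": resp.ravel(),
                }
            )
        )
    out = pd.concat(chunks, ignore_index=True)
    return out.sort_values(["roi_id", "trial_id"], kind="stable").reset_index(drop=True)


def _responses_by_whisker(trials: pd.DataFrame, roi_id) -> dict[str, np.ndarray]:
    sub = trials[trials["roi_id"] == roi_id]
    return {
        wk: grp["evoked_dff"].to_numpy()
        for wk, grp in sub.groupby("whisker", sort=True)
    }


def classify_responsive(
    trials: pd.DataFrame, windows: AnalysisWindows, seed: int = 0
) -> pd.DataFrame:
    """Per-ROI responsiveness: one-sided whisker-vs-blank permutation tests,
    BH-corrected across the nine whiskers.

    Returns one row per ROI with adjusted p per whisker (``p_<whisker>``),
    per-whisker flags (``resp_<whisker>``) and ``is_responsive``.
    """
    windows.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for roi_id, sub in trials.groupby("roi_id", sort=True):
        by_wk = {
            wk: grp["evoked_dff"].to_numpy() for wk, grp in sub.groupby("whisker")
        }
        blank = by_wk.get(BLANK)
        if blank is None or blank.size < 5:
            raise ValueError(f"ROI {roi_id}: needs >= 5 blank trials")
        raw = np.array(
            [
                permutation_mean_test(
                    by_wk[wk], blank, n_perm=windows.n_perm,
                    alternative="greater", rng=rng,
                )
                for wk in WHISKERS
            ]
        )
        adj = fdr_bh(raw)
        flags = adj < windows.alpha
        row = {"roi_id": roi_id, "is_responsive": bool(flags.any())}
        row.update({f"p_{wk}": adj[i] for i, wk in enumerate(WHISKERS)})
        row.update({f"resp_{wk}": bool(flags[i]) for i, wk in enumerate(WHISKERS)})
        rows.append(row)
    return pd.DataFrame(rows)


def receptive_field(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI medians, blank-z-scored medians, and spontaneous activity.

    z_<whisker> = (median evoked to the whisker - mean blank evoked) / SD of
    blank evoked; spontaneous = median blank evoked dF/F.
    """
    rows = []
    for roi_id, sub in trials.groupby("roi_id", sort=True):
        blank = sub.loc[sub["whisker"] == BLANK, "evoked_dff"].to_numpy()
        if blank.size < 2:
            raise ValueError(f"ROI {roi_id}: needs >= 2 blank trials for z-scores")
        mu, sd = blank.mean(), blank.std(ddof=1)
        row = {"roi_id": roi_id, "spontaneous": float(np.median(blank))}
        for wk in WHISKERS:
            vals = sub.loc[sub["whisker"] == wk, "evoked_dff"].to_numpy()
            med = float(np.median(vals)) if vals.size else np.nan
            mean = float(vals.mean()) if vals.size else np.nan
            row[f"median_{wk}"] = med
            row[f"mean_{wk}"] = mean
            if sd == 0:
                row[f"z_{wk}"] = np.nan
            else:
                row[f"z_{wk}"] = (med - mu) / sd
        if sd == 0:
            warnings.warn(f"ROI {roi_id}: blank SD is zero; z undefined", stacklevel=2)
        rows.append(row)
    return pd.DataFrame(rows)


def best_and_equal_best(
    trials: pd.DataFrame,
    rf: pd.DataFrame,
    windows: AnalysisWindows,
    seed: int = 0,
) -> pd.DataFrame:
    """Best whisker and the equal-best set per ROI.

    BW maximizes the mean evoked dF/F (ties to the lexicographically
    smallest label).  Every other whisker enters the eBW set unless the
    two-sided BW-vs-whisker permutation test (BH-corrected across the
    eight comparisons) rejects at alpha.  The test is two-sided because
    "indistinguishable from the BW" is an equality hypothesis, and because
    the BW is selected as the maximum: a one-sided test inherits that
    selection bias and shrinks null eBW sets well below the nominal level.
    """
    windows.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for roi_id, sub in trials.groupby("roi_id", sort=True):
        by_wk = {
            wk: grp["evoked_dff"].to_numpy()
            for wk, grp in sub.groupby("whisker")
            if wk != BLANK
        }
        means = {wk: by_wk[wk].mean() for wk in WHISKERS if wk in by_wk}
        best = max(sorted(means), key=lambda wk: (means[wk], ))  # ties -> smallest label
        # max() keeps the first of equal keys under sorted label order
        others = [wk for wk in WHISKERS if wk in by_wk and wk != best]
        raw = np.array(
            [
                permutation_mean_test(
                    by_wk[best], by_wk[wk], n_perm=windows.n_perm,
                    alternative="two_sided", rng=rng,
                )
                for wk in others
            ]
        )
        adj = fdr_bh(raw) if raw.size else raw
        ebw = {best} | {wk for wk, p in zip(others, adj) if p >= windows.alpha}
        rows.append({"roi_id": roi_id, "bw": best, "ebw_set": frozenset(ebw)})
    return pd.DataFrame(rows)


def build_receptive_fields(
    trials: pd.DataFrame, windows: AnalysisWindows, seed: int = 0
) -> pd.DataFrame:
    """Full receptive-field table: medians/z, responsiveness, BW and eBW.

    BW/eBW are computed for responsive ROIs only (NaN otherwise).
    """
    rf = receptive_field(trials)
    resp = classify_responsive(trials, windows, seed=seed)
    out = rf.merge(resp, on="roi_id")
    responsive_ids = out.loc[out["is_responsive"], "roi_id"]
    sub = trials[trials["roi_id"].isin(responsive_ids)]
    if len(sub):
        bw = best_and_equal_best(sub, rf, windows, seed=seed)
        out = out.merge(bw, on="roi_id", how="left")
    else:
        out["bw"] = None
        out["ebw_set"] = None
    return out


def rank_ordered_rf(rf: pd.DataFrame) -> np.ndarray:
    """Mean rank-ordered tuning curve: per-ROI descending sort of the nine
    z-scored medians, averaged element-wise over ROIs."""
    z = rf[[f"z_{wk}" for wk in WHISKERS]].to_numpy(dtype=float)
    if z.shape[0] == 0:
        raise ValueError("no ROIs")
    ranked = -np.sort(-z, axis=1)
    return ranked.mean(axis=0)


def cw_sw_profile(
    rf: pd.DataFrame, assignment: pd.DataFrame, min_rois_per_column: int = 3
):
    """Responses to the columnar whisker and its four row/arc neighbours.

    Returns ``(per_roi, aggregate)``.  ``per_roi`` has the z-scored response
    to the CW and to the within-row (+/-1 arc) and within-arc (+/-1 row)
    adjacent whiskers; grid-edge neighbours are NaN.  The aggregate
    (mean +/- SEM over ROIs) excludes columns contributing fewer than
    ``min_rois_per_column`` ROIs.
    """
    merged = rf.merge(assignment[["roi_id", "column"]], on="roi_id")
    merged = merged[merged["column"].isin(WHISKERS)]
    if "is_responsive" in merged.columns:
        merged = merged[merged["is_responsive"]]

    offsets = {
        "cw": (0, 0),
        "within_arc_minus_row": (-1, 0),
        "within_arc_plus_row": (1, 0),
        "within_row_minus_arc": (0, -1),
        "within_row_plus_arc": (0, 1),
    }
    rows = []
    for _, r in merged.iterrows():
        cw = r["column"]
        cr, ca = row_arc(cw)
        row = {"roi_id": r["roi_id"], "column": cw}
        for name, (dr, da) in offsets.items():
            rr, aa = cr + dr, ca + da
            if 0 <= rr < 3 and 0 <= aa < 3:
                row[name] = r[f"z_{'CDE'[rr]}{'123'[aa]}"]
            else:
                row[name] = np.nan
        rows.append(row)
    per_roi = pd.DataFrame(rows)
    if per_roi.empty:
        return per_roi, pd.DataFrame()

    counts = per_roi["column"].value_counts()
    keep = counts[counts >= min_rois_per_column].index
    kept = per_roi[per_roi["column"].isin(keep)]
    agg_rows = []
    for name in offsets:
        vals = kept[name].dropna().to_numpy()
        agg_rows.append(
            {
                "position": name,
                "mean": vals.mean() if vals.size else np.nan,
                "sem": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
                "n": int(vals.size),
            }
        )
    return per_roi, pd.DataFrame(agg_rows)
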