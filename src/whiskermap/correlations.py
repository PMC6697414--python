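"""Pairwise signal and noise correlations with distance/column structure.

Signal correlation: Pearson correlation of two ROIs' 9-element mean-
response-per-whisker vectors (each vector z-scored, which leaves the
Pearson correlation unchanged).  Noise correlation: per whisker, the
Pearson correlation of the two ROIs' trial-response vectors (each
z-scored), averaged over the nine whiskers.  Pairs are restricted to
simultaneously imaged, responsive ROIs located within (or above) a barrel;
septal ROIs are excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .session import WHISKERS
from .somatotopy import SEPTUM


def signal_correlation(rf_a, rf_b) -> float:
    """Pearson correlation of two 9-element mean tuning vectors."""
    a = np.asarray(rf_a, dtype=float)
    b = np.asarray(rf_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance tuning vector; correlation undefined", stacklevel=2)
        return np.nan
    za = (a - a.mean()) / a.std()
    zb = (b - b.mean()) / b.std()
    return float(np.dot(za, zb) / a.size)


def noise_correlation(trials_a: dict, trials_b: dict) -> float:
    """Mean over whiskers of the per-whisker trial-response correlation.

    ``trials_a``/``trials_b`` map whisker label to the vector of evoked
    responses across repetitions (aligned trial order).  Zero-variance
    whisker vectors are skipped; if every whisker is skipped the result is
    NaN.
    """
    vals = []
    for wk in WHISKERS:
        if wk not in trials_a or wk not in trials_b:
            continue
        a = np.asarray(trials_a[wk], dtype=float)
        b = np.asarray(trials_b[wk], dtype=float)
        if a.size != b.size:
            raise ValueError(f"whisker {wk}: trial counts differ")
        if a.size < 3:
            raise ValueError(f"whisker {wk}: needs >= 3 trials")
        if a.std() == 0 or b.std() == 0:
            continue
        vals.append(np.corrcoef(a, b)[0, 1])
    return float(np.mean(vals)) if vals else np.nan


def _trial_matrices(trials: pd.DataFrame, roi_ids) -> dict[str, np.ndarray]:
    """Per-whisker (n_rois, n_reps) matrices in a fixed roi order."""
    out = {}
    pivot = trials.pivot(index="roi_id", columns="trial_id", values="evoked_dff")
    pivot = pivot.loc[list(roi_ids)]
    trial_wk = trials.drop_duplicates("trial_id").set_index("trial_id")["whisker"]
    for wk in WHISKERS:
        tids = trial_wk.index[trial_wk == wk]
        out[wk] = pivot[tids].to_numpy(dtype=float)
    return out


def pairwise_table(
    trials: pd.DataFrame,
    rf: pd.DataFrame,
    assignment: pd.DataFrame,
    coords_um: np.ndarray | None = None,
) -> pd.DataFrame:
    """All unordered pairs of responsive, barrel-assigned ROIs.

    ``coords_um`` gives per-ROI centroids aligned with ``rf`` row order; if
    omitted, distances require an ``x_um``/``y_um`` merge upstream.
    Columns: roi_a, roi_b, signal_corr, noise_corr, distance_um, relation,
    boundary_axis.
    """
    merged = rf.merge(assignment[["roi_id", "column"]], on="roi_id")
    if coords_um is not None:
        merged = merged.assign(x_um=coords_um[:, 0], y_um=coords_um[:, 1])
    eligible = merged[
        merged["is_responsive"] & (merged["column"] != SEPTUM)
    ].reset_index(drop=True)
    n = len(eligible)
    if n < 2:
        raise ValueError("need >= 2 responsive, barrel-assigned ROIs")

    roi_ids = eligible["roi_id"].to_numpy()
    sub_trials = trials[trials["roi_id"].isin(roi_ids)]
    mats = _trial_matrices(sub_trials, roi_ids)

    # noise correlation matrix: mean over whiskers of trial-corr matrices
    corr_sum = np.zeros((n, n))
    corr_cnt = np.zeros((n, n))
    for wk in WHISKERS:
        m = mats[wk]
        sd = m.std(axis=1)
        ok = sd > 0
        if ok.sum() < 2:
            continue
        c = np.corrcoef(m[ok])
        idx = np.nonzero(ok)[0]
        corr_sum[np.ix_(idx, idx)] += c
        corr_cnt[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        noise_mat = corr_sum / corr_cnt

    # signal correlation matrix from mean tuning vectors
    tuning = eligible[[f"mean_{wk}" for wk in WHISKERS]].to_numpy(dtype=float)
    sd = tuning.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance tuning vector(s); correlations NaN", stacklevel=2)
    with np.errstate(invalid="ignore"):
        z = (tuning - tuning.mean(axis=1, keepdims=True)) / sd[:, None]
        sig_mat = z @ z.T / tuning.shape[1]

    xy = eligible[["x_um", "y_um"]].to_numpy(dtype=float)
    cols = eligible["column"].to_numpy()
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            same_col = cols[i] == cols[j]
            if same_col:
                axis = "NA"
            elif cols[i][0] == cols[j][0]:
                axis = "within_row"
            elif cols[i][1] == cols[j][1]:
                axis = "within_arc"
            else:
                axis = "NA"
            rows.append(
                {
                    "roi_a": roi_ids[i],
                    "roi_b": roi_ids[j],
                    "signal_corr": sig_mat[i, j],
                    "noise_corr": noise_mat[i, j],
                    "distance_um": float(np.hypot(*(xy[i] - xy[j]))),
                    "relation": "within_column" if same_col else "across_column",
                    "boundary_axis": axis,
                }
            )
    return pd.DataFrame(rows)


def distance_binned_correlations(
    table: pd.DataFrame, bin_width_um: float = 50.0
) -> pd.DataFrame:
    """Mean +/- SEM of signal and noise correlation per (relation, distance
    bin), half-open bins; empty bins are absent (never zero-filled)."""
    if table.empty:
        raise ValueError("empty pair table")
    t = table.copy()
    t["bin"] = np.floor(t["distance_um"] / bin_width_um).astype(int)
    rows = []
    for (rel, b), grp in t.groupby(["relation", "bin"]):
        row = {
            "relation": rel,
            "bin_lo_um": b * bin_width_um,
            "bin_hi_um": (b + 1) * bin_width_um,
            "n": len(grp),
        }
        for kind in ("signal_corr", "noise_corr"):
            v = grp[kind].dropna().to_numpy()
            row[f"mean_{kind}"] = v.mean() if v.size else np.nan
            row[f"sem_{kind}"] = (
                v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["relation", "bin_lo_um"]).reset_index(
        drop=True
    )


def column_referenced_correlation(
    table: pd.DataFrame,
    assignment: pd.DataFrame,
    reference_whisker: str,
    coords: np.ndarray,
    roi_ids,
    kind: str = "signal",
    bin_width_um: float = 75.0,
):
    """Mean correlation of each sample ROI to the reference-column population.

    ``coords`` are reference-frame coordinates aligned with ``roi_ids``.
    Self-pairs are excluded; sample ROIs inside the reference column are
    kept.  Returns ``(per_roi, profile)`` with the profile binned by
    distance from the column center.
    """
    if kind not in ("signal", "noise"):
        raise ValueError(f"unknown kind: {kind!r}")
    col = f"{kind}_corr"
    ref_ids = set(
        assignment.loc[assignment["column"] == reference_whisker, "roi_id"]
    )
    # restrict to reference ROIs that actually appear in the pair table
    in_table = set(table["roi_a"]) | set(table["roi_b"])
    ref_ids &= in_table
    if len(ref_ids) < 2:
        raise ValueError(f"reference column {reference_whisker!r} has < 2 usable ROIs")

    dist = dict(zip(roi_ids, np.hypot(coords[:, 0], coords[:, 1])))
    acc: dict = {}
    for a, b, v in zip(table["roi_a"], table["roi_b"], table[col]):
        if not np.isfinite(v):
            continue
        if b in ref_ids:
            acc.setdefault(a, []).append(v)
        if a in ref_ids:
            acc.setdefault(b, []).append(v)
    per_roi = pd.DataFrame(
        {
            "roi_id": list(acc),
            "mean_corr": [float(np.mean(v)) for v in acc.values()],
        }
    )
    per_roi["dist_um"] = per_roi["roi_id"].map(dist)

    per_roi["bin"] = np.floor(per_roi["dist_um"] / bin_width_um).astype(int)
    rows = []
    for b, grp in per_roi.groupby("bin"):
        v = grp["mean_corr"].to_numpy()
        rows.append(
            {
                "bin_lo_um": b * bin_width_um,
                "bin_hi_um": (b + 1) * bin_width_um,
                "mean_corr": v.mean(),
                "sem": v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan,
                "n": int(v.size),
            }
        )
    profile = pd.DataFrame(rows).sort_values("bin_lo_um").reset_index(drop=True)
    return per_roi.drop(columns="bin"), profile
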