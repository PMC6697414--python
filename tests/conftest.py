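"""Shared fixtures: small synthetic sessions and fast analysis settings."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import whiskermap as wm


@pytest.fixture(scope="session")
def small_session():
    """A small NH-like session with known ground truth."""
    params = replace(
        wm.preset_params("NH_like", 7), n_rois=30, reps_per_stim=20
    )
    bundle, truth = wm.generate_session(params, with_truth=True)
    return bundle, truth


@pytest.fixture(scope="session")
def fast_windows():
    return wm.AnalysisWindows(n_perm=300)


@pytest.fixture(scope="session")
def small_analysis(small_session, fast_windows):
    """Preprocessed trial responses and receptive fields for the small session."""
    bundle, truth = small_session
    dff, filtered = wm.session_dff(bundle)
    trials = wm.evoked_response_per_trial(dff, filtered.stimulus, fast_windows)
    rf = wm.build_receptive_fields(trials, fast_windows, seed=0)
    assignment = wm.assign_columns(filtered.rois, filtered.barrels)
    coords = wm.to_reference_frame(filtered.rois, filtered.barrels, "D2")
    return {
        "bundle": filtered,
        "truth": truth,
        "trials": trials,
        "rf": rf,
        "assignment": assignment,
        "coords": coords,
    }


def make_trial_table(resp_by_whisker: dict, roi_id="roi0", start_trial=0):
    """Build a TrialResponseTable for one ROI from per-whisker response vectors."""
    rows = []
    tid = start_trial
    for wk, vals in resp_by_whisker.items():
        for v in np.asarray(vals, dtype=float):
            rows.append(
                {"roi_id": roi_id, "trial_id": tid, "whisker": wk, "evoked_dff": v}
            )
            tid += 1
    return pd.DataFrame(rows)
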