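"""Signal and noise correlations within and across barrel columns.

Contrasts the two presets: the enriched-like generator attenuates shared
noise across column boundaries, which shows up as lower cross-column noise
correlations at matched distances.
"""

from dataclasses import replace

import whiskermap as wm

windows = wm.AnalysisWindows(n_perm=500)
for name in ("NH_like", "EN_like"):
    params = replace(wm.preset_params(name, seed=5), n_rois=120, reps_per_stim=30)
    bundle = wm.generate_session(params)
    dff, filtered = wm.session_dff(bundle)
    trials = wm.evoked_response_per_trial(dff, filtered.stimulus, windows)
    rf = wm.build_receptive_fields(trials, windows, seed=0)
    assignment = wm.assign_columns(filtered.rois, filtered.barrels)
    coords = wm.to_reference_frame(filtered.rois, filtered.barrels, "D2")
    pairs = wm.pairwise_table(trials, rf, assignment, coords_um=coords)
    print(f"{name}: {len(pairs)} responsive, barrel-assigned pairs")
    for rel, grp in pairs.groupby("relation"):
        print(f"  {rel:>14}: signal r = {grp['signal_corr'].mean():.3f}, "
              f"noise r = {grp['noise_corr'].mean():.3f} (n = {len(grp)})")

print("\nnoise correlations measure shared trial-to-trial variability; a drop "
      "across column borders marks a functional boundary")
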