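"""Generate a synthetic imaging session and inspect its structure.

Builds a normally-housed-like session (9 whiskers + blank, 5-pulse trains,
5 s inter-stimulus interval, 80 s movies at 30 Hz) and writes it to a
plain directory that `read_session` can load back.
"""

from dataclasses import replace
from pathlib import Path

import whiskermap as wm

params = replace(wm.preset_params("NH_like", seed=42), n_rois=40, reps_per_stim=20)
bundle, truth = wm.generate_session(params, with_truth=True)

out = Path("scratch/example_session")
wm.write_session(bundle, out)

print(f"session {bundle.session_id}: {len(bundle.movies)} movies of "
      f"{bundle.movies[0].n_frames} frames at {bundle.frame_rate_hz:g} Hz")
print(f"{len(bundle.stimulus)} trials; label counts:\n"
      f"{bundle.stimulus['whisker'].value_counts().to_string()}")
print(f"{params.n_rois} ROIs; "
      f"{(truth['column'] == truth['preferred_whisker']).mean():.0%} prefer their "
      "columnar whisker (ground truth)")
print(f"written to {out}/ (metadata.json, stimulus.csv, rois.csv, barrels.json, "
      "traces.h5)")
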