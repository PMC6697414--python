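"""Read/write an imaging session to a plain directory layout.

Layout under the session root:

- ``metadata.json``   — session id, layer, condition, frame rate, movie order
- ``stimulus.csv``    — trial_id, movie_id, onset_frame, whisker
- ``rois.csv``        — roi_id, x_um, y_um, nuclear
- ``barrels.json``    — per-barrel label, centroid, polygon, area; row-axis angle
- ``traces.h5``       — one group per movie with ``soma_f`` and optional
  ``neuropil_f`` datasets (float64, ROIs x frames)
- ``masks.json``      — optional per-ROI pixel masks
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .session import (
    Barrel,
    BarrelMap,
    MissingComponentError,
    MovieTrace,
    RoiGeometry,
    SessionBundle,
)

_COMPONENTS = ("metadata.json", "stimulus.csv", "rois.csv", "barrels.json", "traces.h5")


def write_session(bundle: SessionBundle, root_path) -> None:
    """Serialize a validated bundle; raises ValidationError on invalid input."""
    bundle.validate()
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)

    meta = {
        "session_id": bundle.session_id,
        "layer": bundle.layer,
        "condition": bundle.condition,
        "frame_rate_hz": bundle.frame_rate_hz,
        "movie_ids": [m.movie_id for m in bundle.movies],
    }
    (root / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    bundle.stimulus.to_csv(root / "stimulus.csv", index=False)
    bundle.rois.table.to_csv(root / "rois.csv", index=False)

    barrels = {
        "row_axis_angle": bundle.barrels.row_axis_angle,
        "barrels": [
            {
                "label": b.label,
                "centroid": list(map(float, b.centroid_xy)),
                "polygon": np.asarray(b.polygon, dtype=float).tolist(),
                "area_um2": float(b.area_um2),
            }
            for b in bundle.barrels.barrels.values()
        ],
    }
    (root / "barrels.json").write_text(json.dumps(barrels, indent=2, sort_keys=True))

    with h5py.File(root / "traces.h5", "w") as f:
        for m in bundle.movies:
            g = f.create_group(m.movie_id)
            # track_times=False keeps the byte layout deterministic
            g.create_dataset(
                "soma_f",
                data=np.asarray(m.soma_f, dtype=np.float64),
                track_times=False,
            )
            if m.neuropil_f is not None:
                g.create_dataset(
                    "neuropil_f",
                    data=np.asarray(m.neuropil_f, dtype=np.float64),
                    track_times=False,
                )

    if bundle.rois.pixel_masks is not None:
        masks = {
            str(k): np.asarray(v, dtype=int).tolist()
            for k, v in bundle.rois.pixel_masks.items()
        }
        (root / "masks.json").write_text(json.dumps(masks, sort_keys=True))


def read_session(root_path) -> SessionBundle:
    """Load and validate a session written by :func:`write_session`."""
    root = Path(root_path)
    for name in _COMPONENTS:
        if not (root / name).exists():
            raise MissingComponentError(f"missing component: {root / name}")

    meta = json.loads((root / "metadata.json").read_text())
    stimulus = pd.read_csv(root / "stimulus.csv")
    rois_table = pd.read_csv(root / "rois.csv")
    rois_table["nuclear"] = rois_table["nuclear"].astype(bool)

    bj = json.loads((root / "barrels.json").read_text())
    barrels = {
        b["label"]: Barrel(
            label=b["label"],
            centroid_xy=tuple(b["centroid"]),
            polygon=np.asarray(b["polygon"], dtype=float),
            area_um2=b["area_um2"],
        )
        for b in bj["barrels"]
    }
    barrel_map = BarrelMap(barrels=barrels, row_axis_angle=bj["row_axis_angle"])

    movies = []
    with h5py.File(root / "traces.h5", "r") as f:
        for movie_id in meta["movie_ids"]:
            g = f[movie_id]
            movies.append(
                MovieTrace(
                    movie_id=movie_id,
                    soma_f=g["soma_f"][()],
                    neuropil_f=g["neuropil_f"][()] if "neuropil_f" in g else None,
                )
            )

    masks = None
    if (root / "masks.json").exists():
        raw = json.loads((root / "masks.json").read_text())
        masks = {k: np.asarray(v, dtype=int) for k, v in raw.items()}

    bundle = SessionBundle(
        session_id=meta["session_id"],
        layer=meta["layer"],
        condition=meta["condition"],
        frame_rate_hz=meta["frame_rate_hz"],
        movies=movies,
        stimulus=stimulus,
        rois=RoiGeometry(table=rois_table, pixel_masks=masks),
        barrels=barrel_map,
    )
    bundle.validate()
    return bundle
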