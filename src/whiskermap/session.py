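"""Data model for a trial-structured two-photon imaging session.

A session is one imaging field: fluorescence traces for a set of somatic
ROIs collected as a sequence of short movies, a stimulus table giving the
onset frame and whisker identity of every trial (nine whiskers in a 3x3
row/arc grid, plus blank catch trials), the ROI centroids in field
coordinates (micrometres), and the anatomical barrel map that positions the
field over the layer-4 whisker columns.

Coordinate conventions: micrometres, origin at the field's top-left corner,
x rightward, y downward.  Frames are 0-based; time windows are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

ROWS = "CDE"
ARCS = "123"
WHISKERS: tuple[str, ...] = tuple(r + a for r in ROWS for a in ARCS)
BLANK = "BLANK"
STIM_LABELS: tuple[str, ...] = WHISKERS + (BLANK,)

#: number of frames integrated after train onset (1 s at 30 Hz)
DEFAULT_EVOKED_FRAMES = 30
#: number of baseline frames before onset (0.5 s at 30 Hz)
DEFAULT_BASELINE_FRAMES = 15


class ValidationError(ValueError):
    """A bundle field violates one of the documented invariants."""


class MissingComponentError(FileNotFoundError):
    """A required on-disk component of a session is absent."""


def row_arc(whisker: str) -> tuple[int, int]:
    """Integer (row, arc) grid coordinates of a whisker label.

    Rows C/D/E map to 0/1/2 and arcs 1/2/3 to 0/1/2.
    """
    if whisker not in WHISKERS:
        raise ValidationError(f"not a whisker label: {whisker!r}")
    return ROWS.index(whisker[0]), ARCS.index(whisker[1])


def grid_neighbors(whisker: str) -> list[str]:
    """Row/arc neighbours of a whisker on the 3x3 grid (no diagonals)."""
    r, a = row_arc(whisker)
    out = []
    for dr, da in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        rr, aa = r + dr, a + da
        if 0 <= rr < 3 and 0 <= aa < 3:
            out.append(ROWS[rr] + ARCS[aa])
    return out


@dataclass
class MovieTrace:
    """Raw fluorescence traces for one movie: ROIs x frames, arbitrary units."""

    movie_id: str
    soma_f: np.ndarray
    neuropil_f: Optional[np.ndarray] = None

    @property
    def n_frames(self) -> int:
        return self.soma_f.shape[1]

    @property
    def n_rois(self) -> int:
        return self.soma_f.shape[0]

    def validate(self) -> None:
        f = np.asarray(self.soma_f)
        if f.ndim != 2:
            raise ValidationError(f"movie {self.movie_id}: soma_f must be 2-D")
        if not np.all(np.isfinite(f)):
            raise ValidationError(f"movie {self.movie_id}: soma_f must be finite")
        if not np.all(f > 0):
            raise ValidationError(f"movie {self.movie_id}: soma_f must be positive")
        if self.neuropil_f is not None and self.neuropil_f.shape != f.shape:
            raise ValidationError(
                f"movie {self.movie_id}: neuropil_f shape {self.neuropil_f.shape}"
                f" != soma_f shape {f.shape}"
            )


@dataclass
class RoiGeometry:
    """Per-ROI centroids (um, field coordinates) and flags.

    ``table`` has columns roi_id, x_um, y_um, nuclear.  ``pixel_masks``
    optionally maps roi_id to an (n, 2) array of (row, col) pixels.
    """

    table: pd.DataFrame
    pixel_masks: Optional[dict] = None

    @property
    def roi_ids(self) -> np.ndarray:
        return self.table["roi_id"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x_um", "y_um"]].to_numpy(dtype=float)

    def validate(self) -> None:
        req = {"roi_id", "x_um", "y_um", "nuclear"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValidationError(f"rois table missing columns: {sorted(missing)}")
        ids = self.table["roi_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate roi_id: {dup!r}")


@dataclass
class Barrel:
    label: str
    centroid_xy: tuple[float, float]
    polygon: np.ndarray  # (n_vertices, 2) um, closed implicitly
    area_um2: float


@dataclass
class BarrelMap:
    """Anatomical barrel centroids/boundaries and the row-axis orientation.

    ``row_axis_angle`` is the angle (radians) of the within-row anatomical
    axis in field coordinates, measured from +x toward +y.
    """

    barrels: dict[str, Barrel]
    row_axis_angle: float = 0.0

    def centroid(self, whisker: str) -> np.ndarray:
        return np.asarray(self.barrels[whisker].centroid_xy, dtype=float)

    def validate(self) -> None:
        for label, b in self.barrels.items():
            if label not in WHISKERS:
                raise ValidationError(f"barrel label outside 3x3 grid: {label!r}")
            if b.area_um2 <= 0:
                raise ValidationError(f"barrel {label}: area must be > 0")
            poly = np.asarray(b.polygon, dtype=float)
            if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
                raise ValidationError(f"barrel {label}: polygon must be (n>=3, 2)")
            from shapely.geometry import Polygon

            if not Polygon(poly).is_valid:
                raise ValidationError(f"barrel {label}: polygon self-intersects")


@dataclass
class SessionBundle:
    """One imaging field: traces, stimulus table, ROI geometry, barrel map."""

    session_id: str
    layer: str  # "L2/3" or "L4"
    condition: str  # "NH" or "EN"
    movies: list[MovieTrace]
    stimulus: pd.DataFrame  # trial_id, movie_id, onset_frame, whisker
    rois: RoiGeometry
    barrels: BarrelMap
    frame_rate_hz: float = 30.0

    def movie(self, movie_id: str) -> MovieTrace:
        for m in self.movies:
            if m.movie_id == movie_id:
                return m
        raise KeyError(movie_id)

    def validate(self, evoked_frames: int = DEFAULT_EVOKED_FRAMES) -> None:
        if self.layer not in ("L2/3", "L4"):
            raise ValidationError(f"layer must be L2/3 or L4, got {self.layer!r}")
        if self.condition not in ("NH", "EN"):
            raise ValidationError(f"condition must be NH or EN, got {self.condition!r}")
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be positive")
        if not self.movies:
            raise ValidationError("session has no movies")
        n_rois = self.movies[0].n_rois
        for m in self.movies:
            m.validate()
            if m.n_rois != n_rois:
                raise ValidationError(
                    f"movie {m.movie_id}: ROI count {m.n_rois} != {n_rois}"
                )
        self.rois.validate()
        if len(self.rois.table) != n_rois:
            raise ValidationError(
                f"rois table has {len(self.rois.table)} rows, traces have {n_rois}"
            )
        self.barrels.validate()
        self._validate_stimulus(evoked_frames)

    def _validate_stimulus(self, evoked_frames: int) -> None:
        stim = self.stimulus
        req = {"trial_id", "movie_id", "onset_frame", "whisker"}
        missing = req - set(stim.columns)
        if missing:
            raise ValidationError(f"stimulus table missing columns: {sorted(missing)}")
        if stim["trial_id"].duplicated().any():
            raise ValidationError("duplicate trial_id in stimulus table")
        bad = set(stim["whisker"]) - set(STIM_LABELS)
        if bad:
            raise ValidationError(f"invalid whisker labels: {sorted(bad)}")
        absent = set(STIM_LABELS) - set(stim["whisker"])
        if absent:
            raise ValidationError(f"stimulus labels never presented: {sorted(absent)}")
        frames = {m.movie_id: m.n_frames for m in self.movies}
        for _, row in stim.iterrows():
            if row["movie_id"] not in frames:
                raise ValidationError(
                    f"trial {row['trial_id']}: unknown movie {row['movie_id']!r}"
                )
            onset = int(row["onset_frame"])
            if onset < 0 or onset + evoked_frames > frames[row["movie_id"]]:
                raise ValidationError(
                    f"trial {row['trial_id']}: evoked window [{onset},"
                    f" {onset + evoked_frames}) overruns movie {row['movie_id']!r}"
                )
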