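"""Raw fluorescence to neuropil-corrected dF/F.

Per-movie recipe: subtract the scaled neuropil signal (weight ``r``) from
the somatic trace, smooth with a trailing 4-frame moving median, take the
baseline F0 as the 20th percentile of the whole-movie trace, and form
dF/F = (F_t - F0)/F0.  Movies whose mean brightness decays by more than
~10 percent within the movie (imaging errors) are excluded first.

The neuropil mask for an ROI is a 10-pixel-wide square ring starting two
pixels out (Chebyshev distance in [2, 12)), minus any somatic pixels and
minus pixels whose trace correlates with any soma trace at Pearson
r > 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .session import SessionBundle


@dataclass
class NeuropilModel:
    r_weight: float = 0.3
    ring_inner_px: int = 2
    ring_width_px: int = 10
    exclusion_corr_threshold: float = 0.2

    def validate(self) -> None:
        if not 0.0 <= self.r_weight <= 1.0:
            raise ValueError("r_weight must be in [0, 1]")
        if self.ring_inner_px < 1 or self.ring_width_px < 1:
            raise ValueError("ring parameters must be positive integers")


@dataclass
class DffMatrix:
    """Per-movie dF/F (ROIs x frames) with the baselines used."""

    dff: dict[str, np.ndarray]
    f0: dict[str, np.ndarray]
    excluded_movie_ids: list[str] = field(default_factory=list)
    frame_rate_hz: float = 30.0
    roi_ids: np.ndarray | None = None


def temporal_median_filter(trace: np.ndarray, window: int = 4) -> np.ndarray:
    """Trailing moving median: element i is the median of the window ending at i.

    The first ``window - 1`` elements use the available prefix.  Works on a
    1-D trace or an ROIs x frames matrix (filtered along the last axis).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return trace.copy()
    squeeze = trace.ndim == 1
    mat = np.atleast_2d(trace)
    if mat.shape[1] < window:
        raise ValueError("trace shorter than window")
    # true median (mean of middle pair for even windows), trailing alignment
    sw = sliding_window_view(mat, window, axis=1)
    out = np.empty_like(mat)
    out[:, window - 1 :] = np.median(sw, axis=2)
    for i in range(window - 1):
        out[:, i] = np.median(mat[:, : i + 1], axis=1)
    return out[0] if squeeze else out


def neuropil_correct(soma_f, neuropil_f, r_weight: float) -> np.ndarray:
    """soma - r * neuropil, elementwise."""
    soma_f = np.asarray(soma_f, dtype=float)
    neuropil_f = np.asarray(neuropil_f, dtype=float)
    if soma_f.shape != neuropil_f.shape:
        raise ValueError(
            f"length mismatch: soma {soma_f.shape} vs neuropil {neuropil_f.shape}"
        )
    if r_weight == 0:
        return soma_f.copy()
    return soma_f - r_weight * neuropil_f


def compute_dff(movie_trace, percentile: float = 20.0):
    """(dF/F, F0) with F0 the given percentile of the whole-movie trace.

    Uses the linear-interpolation percentile convention.  Accepts a 1-D
    trace or an ROIs x frames matrix (per-row baselines).
    """
    trace = np.asarray(movie_trace, dtype=float)
    squeeze = trace.ndim == 1
    mat = np.atleast_2d(trace)
    f0 = np.percentile(mat, percentile, axis=1)
    bad = np.nonzero(f0 <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive F0 for ROI index(es) {bad.tolist()}: "
            "neuropil over-correction or invalid trace"
        )
    dff = (mat - f0[:, None]) / f0[:, None]
    if squeeze:
        return dff[0], float(f0[0])
    return dff, f0


def _brightness_drop(soma_f: np.ndarray) -> float:
    """Fractional drop of the ROI-averaged trace: first vs last frame decile."""
    mean_trace = soma_f.mean(axis=0)
    n = mean_trace.size
    dec = max(1, n // 10)
    first = mean_trace[:dec].mean()
    last = mean_trace[-dec:].mean()
    if first <= 0:
        return 0.0
    return (first - last) / first


def exclude_dim_movies(bundle: SessionBundle, drop_threshold: float = 0.10):
    """Drop movies whose mean brightness decays by more than the threshold.

    Returns ``(filtered_bundle, excluded_movie_ids)``; stimulus rows for
    excluded movies are removed as well.
    """
    if not bundle.movies:
        raise ValueError("session has no movies")
    excluded = [
        m.movie_id for m in bundle.movies if _brightness_drop(m.soma_f) > drop_threshold
    ]
    if not excluded:
        return bundle, []
    kept = [m for m in bundle.movies if m.movie_id not in excluded]
    if not kept:
        raise ValueError("all movies excluded by brightness criterion")
    stim = bundle.stimulus[~bundle.stimulus["movie_id"].isin(excluded)].reset_index(
        drop=True
    )
    out = SessionBundle(
        session_id=bundle.session_id,
        layer=bundle.layer,
        condition=bundle.condition,
        frame_rate_hz=bundle.frame_rate_hz,
        movies=kept,
        stimulus=stim,
        rois=bundle.rois,
        barrels=bundle.barrels,
    )
    return out, excluded


def build_neuropil_mask(roi_mask, all_soma_masks, movie, model: NeuropilModel):
    """Square ring of neuropil pixels around an ROI, minus somata and
    soma-correlated pixels.

    ``movie`` is a (frames, rows, cols) pixel array.  Returns a set of
    (row, col) pixels; an empty set (with a warning) signals that the
    caller should fall back to r = 0 for this ROI.
    """
    model.validate()
    roi_px = np.asarray(sorted(roi_mask), dtype=int)
    movie = np.asarray(movie, dtype=float)
    _, n_rows, n_cols = movie.shape

    inner = model.ring_inner_px
    outer = inner + model.ring_width_px
    candidates = set()
    for r, c in roi_px:
        for dr in range(-outer + 1, outer):
            for dc in range(-outer + 1, outer):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    candidates.add((rr, cc))
    # Chebyshev distance to the ROI mask must lie in [inner, outer)
    ring = set()
    for px in candidates:
        d = min(max(abs(px[0] - r), abs(px[1] - c)) for r, c in roi_px)
        if inner <= d < outer:
            ring.add(px)

    soma_union = set()
    for mask in all_soma_masks:
        soma_union.update((int(r), int(c)) for r, c in mask)
    ring -= soma_union

    if ring:
        soma_traces = []
        for mask in all_soma_masks:
            px = np.asarray(sorted(mask), dtype=int)
            soma_traces.append(movie[:, px[:, 0], px[:, 1]].mean(axis=1))
        soma_traces = np.asarray(soma_traces)
        keep = set()
        for px in ring:
            t = movie[:, px[0], px[1]]
            if t.std() == 0:
                keep.add(px)
                continue
            rmax = max(
                np.corrcoef(t, s)[0, 1] if s.std() > 0 else 0.0
                for s in soma_traces
            )
            if rmax <= model.exclusion_corr_threshold:
                keep.add(px)
        ring = keep

    if not ring:
        warnings.warn(
            "empty neuropil mask; falling back to r_weight = 0 for this ROI",
            stacklevel=2,
        )
    return ring


def session_dff(
    bundle: SessionBundle,
    r_weight: float = 0.0,
    median_window: int = 4,
    percentile: float = 20.0,
    drop_threshold: float = 0.10,
):
    """Full preprocessing for one session.

    Order: movie-brightness exclusion, neuropil subtraction (when neuropil
    traces are present and r > 0), trailing median filter, per-movie dF/F.
    Returns ``(DffMatrix, filtered_bundle)``.
    """
    filtered, excluded = exclude_dim_movies(bundle, drop_threshold)
    dff: dict[str, np.ndarray] = {}
    f0s: dict[str, np.ndarray] = {}
    for m in filtered.movies:
        f = np.asarray(m.soma_f, dtype=float)
        if r_weight > 0 and m.neuropil_f is not None:
            f = neuropil_correct(f, m.neuropil_f, r_weight)
        f = temporal_median_filter(f, median_window)
        try:
            d, f0 = compute_dff(f, percentile)
        except ValueError as err:
            raise ValueError(f"movie {m.movie_id}: {err}") from err
        dff[m.movie_id] = d
        f0s[m.movie_id] = np.atleast_1d(f0)
    mat = DffMatrix(
        dff=dff,
        f0=f0s,
        excluded_movie_ids=excluded,
        frame_rate_hz=filtered.frame_rate_hz,
        roi_ids=filtered.rois.roi_ids,
    )
    return mat, filtered
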