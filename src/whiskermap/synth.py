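"""Synthetic imaging sessions with the statistical structure the pipeline assumes.

The generator emulates one imaging field over a 3x3 barrel grid: ROIs are
scattered uniformly over the field, each is assigned a preferred whisker
(its column's whisker with probability ``p_cw``, otherwise a grid
neighbour — the salt-and-pepper control), evoked transients follow a
GCaMP6s-like difference-of-exponentials kernel summed over a five-pulse
train (100 ms spacing), and trial-to-trial variability combines private
per-frame Gaussian noise with a shared latent factor whose cross-column
weight is attenuated by ``boundary_attenuation``.  Stimuli are the nine
whiskers plus a blank, interleaved in random order at a 5 s inter-stimulus
interval, ``reps_per_stim`` repetitions each, packaged as 80 s movies.

Two presets bracket the study conditions: ``NH_like`` (looser columnar
tuning, no correlation boundary at column edges) and ``EN_like`` (higher
columnar-whisker preference, row-axis-sharpened tuning, attenuated
cross-column shared noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .session import (
    BLANK,
    STIM_LABELS,
    WHISKERS,
    Barrel,
    BarrelMap,
    MovieTrace,
    RoiGeometry,
    SessionBundle,
    grid_neighbors,
    row_arc,
)

MOVIE_FRAMES = 2400  # 80 s at 30 Hz
ISI_FRAMES = 150  # 5 s inter-stimulus interval
FIRST_ONSET = 30  # first trial onset within each movie
TRIALS_PER_MOVIE = 16


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters; defaults reproduce the study's trial structure."""

    seed: int = 0
    n_rois: int = 100
    field_size_um: tuple[float, float] = (400.0, 400.0)
    barrel_spacing_um: float = 300.0
    barrel_radius_um: float = 151.0
    reps_per_stim: int = 60
    p_cw: float = 0.65
    sigma_row: float = 1.0
    sigma_arc: float = 1.0
    amp_mean: float = 0.03
    amp_sd: float = 0.01
    tau_rise_s: float = 0.1
    tau_decay_s: float = 1.0
    spont_rate_hz: float = 0.05
    private_noise_sd: float = 0.3
    shared_loading: float = 0.2
    boundary_attenuation: float = 1.0
    f0_baseline: float = 1000.0
    frame_rate_hz: float = 30.0
    layer: str = "L2/3"
    condition: str = "NH"

    def validate(self) -> None:
        if not 0.0 <= self.p_cw <= 1.0:
            raise ValueError("p_cw must be in [0, 1]")
        if not 0.0 <= self.boundary_attenuation <= 1.0:
            raise ValueError("boundary_attenuation must be in [0, 1]")
        for name in ("sigma_row", "sigma_arc", "tau_rise_s", "tau_decay_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("private_noise_sd", "amp_sd", "spont_rate_hz", "shared_loading"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_rois <= 0:
            raise ValueError("n_rois must be positive")


def preset_params(name: str, seed: int) -> SynthParams:
    """Parameters for the normally-housed-like or enriched-like condition."""
    base = SynthParams(seed=seed)
    if name == "NH_like":
        return replace(base, p_cw=0.65, boundary_attenuation=1.0,
                       sigma_row=1.0, sigma_arc=1.0, condition="NH")
    if name == "EN_like":
        return replace(base, p_cw=0.85, boundary_attenuation=0.5,
                       sigma_row=0.6, sigma_arc=1.0, condition="EN")
    raise ValueError(f"unknown preset: {name!r}")


def generate_barrel_map(params: SynthParams, n_vertices: int = 48) -> BarrelMap:
    """3x3 grid of circular barrels on a square lattice centred in the field.

    Rows C/D/E run along +y, arcs 1/2/3 along +x, so the within-row axis is
    horizontal (row_axis_angle = 0) by construction.  Each circle is clipped
    to its lattice cell so neighbouring barrels never overlap (real traced
    barrel boundaries are disjoint); at the default radius/spacing the
    clipped slivers are a negligible fraction of the area.
    """
    from shapely.geometry import box

    cx = params.field_size_um[0] / 2.0
    cy = params.field_size_um[1] / 2.0
    sp = params.barrel_spacing_um
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    circle = params.barrel_radius_um * np.column_stack([np.cos(theta), np.sin(theta)])
    barrels = {}
    for label in WHISKERS:
        r, a = row_arc(label)
        centroid = (
            cx + (a - 1) * sp,
            cy + (r - 1) * sp,
        )
        poly = Polygon(circle + np.asarray(centroid))
        if params.barrel_radius_um > sp / 2.0:
            cell = box(
                centroid[0] - sp / 2.0,
                centroid[1] - sp / 2.0,
                centroid[0] + sp / 2.0,
                centroid[1] + sp / 2.0,
            )
            poly = poly.intersection(cell)
        coords = np.asarray(poly.exterior.coords)[:-1]
        barrels[label] = Barrel(label, centroid, coords, poly.area)
    return BarrelMap(barrels=barrels, row_axis_angle=0.0)


def _pulse_kernel(params: SynthParams) -> np.ndarray:
    """Single-pulse difference-of-exponentials kernel, unit peak.

    Truncated at ISI minus the baseline window (with margin for the
    4-frame trailing median) so a trial's transient has fully decayed
    before the next trial's baseline frames begin.
    """
    n = ISI_FRAMES - 15 - 4
    t = np.arange(n) / params.frame_rate_hz
    k = np.exp(-t / params.tau_decay_s) - np.exp(-t / params.tau_rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel: tau_rise >= tau_decay")
    return k / peak


def _train_kernel(params: SynthParams) -> np.ndarray:
    """Five-pulse train kernel (pulses 100 ms apart), truncated like the pulse."""
    pulse = _pulse_kernel(params)
    n = len(pulse)
    step = int(round(0.1 * params.frame_rate_hz))
    out = np.zeros(n)
    for p in range(5):
        off = p * step
        out[off:] += pulse[: n - off]
    return out


def _assign_column(xy: np.ndarray, barrels: BarrelMap) -> list[str]:
    """Column label per ROI: containing barrel, else nearest centroid."""
    polys = {lab: Polygon(b.polygon) for lab, b in barrels.barrels.items()}
    cents = {lab: np.asarray(b.centroid_xy) for lab, b in barrels.barrels.items()}
    out = []
    for x, y in xy:
        p = Point(float(x), float(y))
        hit = [lab for lab, poly in polys.items() if poly.covers(p)]
        if hit:
            out.append(hit[0])
        else:
            d = {lab: np.hypot(*(c - (x, y))) for lab, c in cents.items()}
            out.append(min(d, key=d.get))
    return out


def _stimulus_schedule(params: SynthParams, rng: np.random.Generator) -> pd.DataFrame:
    labels = np.repeat(np.asarray(STIM_LABELS, dtype=object), params.reps_per_stim)
    rng.shuffle(labels)
    n_trials = len(labels)
    idx = np.arange(n_trials)
    return pd.DataFrame(
        {
            "trial_id": idx,
            "movie_id": [f"m{int(i):03d}" for i in idx // TRIALS_PER_MOVIE],
            "onset_frame": FIRST_ONSET + (idx % TRIALS_PER_MOVIE) * ISI_FRAMES,
            "whisker": labels,
        }
    )


def generate_session(params: SynthParams, with_truth: bool = False):
    """Generate a full session; optionally also return the ground truth.

    Draw order is fixed (ROI placement, tuning, trial order, noise) so the
    same parameters and seed give byte-identical output.  The returned
    truth table (when requested) has one row per ROI with its column label
    and preferred whisker.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    barrels = generate_barrel_map(params)

    # --- ROI placement ---
    w, h = params.field_size_um
    xy = rng.uniform(low=(0.0, 0.0), high=(w, h), size=(params.n_rois, 2))
    columns = _assign_column(xy, barrels)

    # --- tuning ---
    preferred = []
    for cw in columns:
        if rng.uniform() < params.p_cw:
            preferred.append(cw)
        else:
            nb = grid_neighbors(cw)
            preferred.append(nb[rng.integers(len(nb))])
    amp_roi = np.abs(rng.normal(params.amp_mean, params.amp_sd, size=params.n_rois))

    # amplitude of each ROI's response to each whisker (Gaussian in grid offsets)
    pref_ra = np.array([row_arc(p) for p in preferred], dtype=float)
    stim_ra = np.array([row_arc(wk) for wk in WHISKERS], dtype=float)
    d_row = stim_ra[None, :, 0] - pref_ra[:, None, 0]
    d_arc = stim_ra[None, :, 1] - pref_ra[:, None, 1]
    tuning = amp_roi[:, None] * np.exp(
        -(d_row**2 / (2 * params.sigma_row**2) + d_arc**2 / (2 * params.sigma_arc**2))
    )  # (n_rois, 9)

    # --- trial order ---
    stim = _stimulus_schedule(params, rng)
    n_trials = len(stim)
    n_movies = int(math.ceil(n_trials / TRIALS_PER_MOVIE))

    # --- traces: evoked signal + spontaneous events + structured noise ---
    kernel = _train_kernel(params)
    pulse = _pulse_kernel(params)
    klen = len(kernel)
    whisker_idx = {wk: i for i, wk in enumerate(WHISKERS)}
    col_idx = np.array([whisker_idx[c] for c in columns])
    b = params.boundary_attenuation
    total_frames = n_movies * MOVIE_FRAMES

    # spontaneous event times over the whole session, per ROI
    spont = []
    for _ in range(params.n_rois):
        n_ev = rng.poisson(params.spont_rate_hz * total_frames / params.frame_rate_hz)
        times = np.sort(rng.integers(0, total_frames, size=n_ev))
        amps = np.abs(rng.normal(params.amp_mean, params.amp_sd, size=n_ev))
        spont.append((times, amps))

    movies = []
    for mi in range(n_movies):
        movie_id = f"m{mi:03d}"
        signal = np.zeros((params.n_rois, MOVIE_FRAMES))
        sub = stim[stim["movie_id"] == movie_id]
        for onset, wk in zip(sub["onset_frame"], sub["whisker"]):
            if wk == BLANK:
                continue
            amp = tuning[:, whisker_idx[wk]]
            stop = min(onset + klen, MOVIE_FRAMES)
            signal[:, onset:stop] += amp[:, None] * kernel[None, : stop - onset]
        lo = mi * MOVIE_FRAMES
        for ri, (times, amps) in enumerate(spont):
            sel = (times >= lo) & (times < lo + MOVIE_FRAMES)
            for t, a in zip(times[sel] - lo, amps[sel]):
                stop = min(t + len(pulse), MOVIE_FRAMES)
                signal[ri, t:stop] += a * pulse[: stop - t]

        # shared latent: global factor mixed with per-column factors so that
        # within-column shared covariance is s^2 and cross-column is b*s^2
        g = rng.standard_normal(MOVIE_FRAMES)
        c = rng.standard_normal((9, MOVIE_FRAMES))
        shared = params.shared_loading * (
            math.sqrt(b) * g[None, :] + math.sqrt(1.0 - b) * c[col_idx, :]
        )
        private = params.private_noise_sd * rng.standard_normal(
            (params.n_rois, MOVIE_FRAMES)
        )
        f = params.f0_baseline * (1.0 + signal + shared + private)
        np.clip(f, 1e-6, None, out=f)
        movies.append(MovieTrace(movie_id=movie_id, soma_f=f))

    rois = RoiGeometry(
        table=pd.DataFrame(
            {
                "roi_id": [f"roi{ri:04d}" for ri in range(params.n_rois)],
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
                "nuclear": False,
            }
        )
    )
    bundle = SessionBundle(
        session_id=f"synth-{params.condition}-{params.seed}",
        layer=params.layer,
        condition=params.condition,
        frame_rate_hz=params.frame_rate_hz,
        movies=movies,
        stimulus=stim,
        rois=rois,
        barrels=barrels,
    )
    if not with_truth:
        return bundle
    truth = pd.DataFrame(
        {
            "roi_id": rois.table["roi_id"],
            "column": columns,
            "preferred_whisker": preferred,
            "amplitude": amp_roi,
        }
    )
    return bundle, truth
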