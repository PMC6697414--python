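"""ROIs in the anatomical column reference frame; map topography statistics.

ROIs are assigned to the barrel column whose boundary polygon contains
their centroid (boundary-inclusive) or to the septum otherwise.  To pool
fields, coordinates are translated so a reference column's centroid is the
origin and rotated so the within-row anatomical axis is horizontal.  Point
representations and tuned-fraction profiles are computed in half-open
75 um distance bins from the reference column center.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from shapely.geometry import Point, Polygon
from sklearn.cluster import KMeans

from .session import BarrelMap, RoiGeometry

SEPTUM = "SEPTUM"


def assign_columns(rois: RoiGeometry, barrels: BarrelMap) -> pd.DataFrame:
    """Column membership per ROI (point-in-polygon, boundary inclusive).

    Columns: roi_id, column (whisker label or SEPTUM), in_barrel,
    nearest_centroid_label, dist_to_centroid_um.
    """
    polys = {lab: Polygon(b.polygon) for lab, b in barrels.barrels.items()}
    cents = {lab: np.asarray(b.centroid_xy) for lab, b in barrels.barrels.items()}
    rows = []
    for roi_id, x, y in zip(rois.roi_ids, *rois.centroids.T):
        p = Point(float(x), float(y))
        hits = [lab for lab, poly in polys.items() if poly.covers(p)]
        if len(hits) > 1:
            raise ValueError(
                f"ROI {roi_id} inside multiple barrels {hits}: invalid map"
            )
        dists = {lab: float(np.hypot(*(c - (x, y)))) for lab, c in cents.items()}
        nearest = min(sorted(dists), key=dists.get)
        if hits:
            rows.append(
                {
                    "roi_id": roi_id,
                    "column": hits[0],
                    "in_barrel": True,
                    "nearest_centroid_label": nearest,
                    "dist_to_centroid_um": dists[hits[0]],
                }
            )
        else:
            rows.append(
                {
                    "roi_id": roi_id,
                    "column": SEPTUM,
                    "in_barrel": False,
                    "nearest_centroid_label": nearest,
                    "dist_to_centroid_um": dists[nearest],
                }
            )
    return pd.DataFrame(rows)


def to_reference_frame(
    rois: RoiGeometry | np.ndarray, barrels: BarrelMap, reference_whisker: str
) -> np.ndarray:
    """ROI coordinates relative to a reference column, row axis horizontal.

    Translates so the reference barrel centroid is the origin, then rotates
    by minus the row-axis angle so the within-row axis lies along +x
    (toward higher arcs).  An isometry by construction.
    """
    if reference_whisker not in barrels.barrels:
        raise ValueError(f"missing reference barrel: {reference_whisker!r}")
    xy = rois.centroids if isinstance(rois, RoiGeometry) else np.asarray(rois, float)
    d = xy - barrels.centroid(reference_whisker)
    theta = barrels.row_axis_angle
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, s], [-s, c]])  # rotation by -theta
    return d @ rot.T


def _bin_index(dist: np.ndarray, bin_width: float) -> np.ndarray:
    return np.floor(dist / bin_width).astype(int)


def point_representation(
    rf: pd.DataFrame,
    coords: np.ndarray,
    reference_whisker: str,
    bin_width_um: float = 75.0,
) -> pd.DataFrame:
    """Mean z-scored response to a reference whisker vs distance from its
    column center, over responsive ROIs, in half-open distance bins."""
    mask = rf["is_responsive"].to_numpy(bool)
    z = rf[f"z_{reference_whisker}"].to_numpy(float)[mask]
    dist = np.hypot(coords[mask, 0], coords[mask, 1])
    ok = np.isfinite(z)
    z, dist = z[ok], dist[ok]
    if z.size == 0:
        return pd.DataFrame(
            columns=["bin_lo_um", "bin_hi_um", "mean_z", "sem", "n"]
        )
    idx = _bin_index(dist, bin_width_um)
    rows = []
    for b in range(idx.max() + 1):
        vals = z[idx == b]
        rows.append(
            {
                "bin_lo_um": b * bin_width_um,
                "bin_hi_um": (b + 1) * bin_width_um,
                "mean_z": vals.mean() if vals.size else np.nan,
                "sem": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def normalized_polar_coordinates(
    coords: np.ndarray, barrels: BarrelMap, reference_whisker: str
) -> pd.DataFrame:
    """Angle from the +row axis and radius as a fraction of the mean column
    radius (from barrel areas, assuming circularity)."""
    radius = mean_barrel_radius(barrels)
    if radius <= 0:
        raise ValueError("reference column radius must be positive")
    ang = np.arctan2(coords[:, 1], coords[:, 0])
    frac = np.hypot(coords[:, 0], coords[:, 1]) / radius
    return pd.DataFrame({"angle_rad": ang, "radius_fraction": frac})


def fraction_tuned_by_distance(
    rf: pd.DataFrame,
    coords: np.ndarray,
    reference_whisker: str,
    measure: str = "eBW",
    bin_width_um: float = 75.0,
) -> pd.DataFrame:
    """Fraction of responsive ROIs tuned to the reference whisker per
    distance bin.  ``measure="BW"``: the reference is the best whisker;
    ``"eBW"``: the reference is among the equal-best whiskers."""
    if measure not in ("BW", "eBW"):
        raise ValueError(f"unknown measure: {measure!r}")
    mask = rf["is_responsive"].to_numpy(bool)
    sub = rf[mask]
    dist = np.hypot(coords[mask, 0], coords[mask, 1])
    if measure == "BW":
        tuned = (sub["bw"] == reference_whisker).to_numpy()
    else:
        tuned = np.array(
            [
                (reference_whisker in s) if isinstance(s, frozenset) else False
                for s in sub["ebw_set"]
            ]
        )
    if len(sub) == 0:
        return pd.DataFrame(columns=["bin_lo_um", "bin_hi_um", "fraction", "tuned", "n"])
    idx = _bin_index(dist, bin_width_um)
    rows = []
    for b in range(idx.max() + 1):
        in_bin = idx == b
        n = int(in_bin.sum())
        t = int(tuned[in_bin].sum())
        rows.append(
            {
                "bin_lo_um": b * bin_width_um,
                "bin_hi_um": (b + 1) * bin_width_um,
                "fraction": t / n if n else np.nan,
                "tuned": t,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def compare_tuned_fractions(
    a_tuned: int, a_total: int, b_tuned: int, b_total: int
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 tuned/untuned table."""
    if a_total <= 0 or b_total <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= a_tuned <= a_total and 0 <= b_tuned <= b_total):
        raise ValueError("tuned counts must lie in [0, total]")
    table = [[a_tuned, a_total - a_tuned], [b_tuned, b_total - b_tuned]]
    odds, p = fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def kmeans_spatial_bins(
    coords: np.ndarray,
    k: int,
    seed: int = 0,
    values: np.ndarray | None = None,
    n_init: int = 10,
):
    """k-means spatial binning of reference-frame coordinates.

    Returns ``(labels, per_bin)`` where per_bin has the bin centroid, count
    and (when ``values`` is given) the per-bin mean of the statistic.
    """
    coords = np.asarray(coords, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(coords):
        raise ValueError("k exceeds number of ROIs")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(coords)
    labels = km.labels_
    rows = []
    for b in range(k):
        sel = labels == b
        row = {
            "bin": b,
            "x_um": km.cluster_centers_[b, 0],
            "y_um": km.cluster_centers_[b, 1],
            "n": int(sel.sum()),
        }
        if values is not None:
            v = np.asarray(values, float)[sel]
            v = v[np.isfinite(v)]
            row["mean_value"] = v.mean() if v.size else np.nan
        rows.append(row)
    return labels, pd.DataFrame(rows)


def barrel_radius_from_area(area_um2):
    """Radius of a circle with the given area: sqrt(area / pi)."""
    area = np.asarray(area_um2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    out = np.sqrt(area / np.pi)
    return float(out) if out.ndim == 0 else out


def mean_barrel_radius(barrels: BarrelMap) -> float:
    """Mean radius over the nine barrels, from areas assuming circularity."""
    areas = [b.area_um2 for b in barrels.barrels.values()]
    return float(np.mean(barrel_radius_from_area(np.asarray(areas))))
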