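"""Column assignment, reference-frame geometry, point representations, tuning maps."""

import itertools

import numpy as np
import pandas as pd
import pytest

import whiskermap as wm
from whiskermap.session import Barrel, BarrelMap


@pytest.fixture(scope="module")
def barrel_map():
    return wm.generate_barrel_map(wm.SynthParams())


def _rois(points):
    return wm.RoiGeometry(
        table=pd.DataFrame(
            {
                "roi_id": [f"r{i}" for i in range(len(points))],
                "x_um": [p[0] for p in points],
                "y_um": [p[1] for p in points],
                "nuclear": False,
            }
        )
    )


class TestAssignColumns:
    def test_centroid_inside_distance_zero(self, barrel_map):
        c = barrel_map.centroid("D2")
        out = wm.assign_columns(_rois([c]), barrel_map)
        assert out["column"].iloc[0] == "D2"
        assert out["in_barrel"].iloc[0]
        assert out["dist_to_centroid_um"].iloc[0] == pytest.approx(0.0)

    def test_midway_point_is_septum(self, barrel_map):
        a, b = barrel_map.centroid("D2"), barrel_map.centroid("D3")
        mid = (a + b) / 2  # 150 um from each centroid with 151 um radius barrels
        mid[1] += 160.0  # push off the straight line, outside both circles
        out = wm.assign_columns(_rois([mid]), barrel_map)
        assert out["column"].iloc[0] == wm.SEPTUM
        assert not out["in_barrel"].iloc[0]

    def test_boundary_vertex_inside(self, barrel_map):
        vertex = barrel_map.barrels["D2"].polygon[0]
        out = wm.assign_columns(_rois([tuple(vertex)]), barrel_map)
        assert out["column"].iloc[0] == "D2"

    def test_overlapping_barrels_error(self):
        sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], dtype=float)
        barrels = {
            "D2": Barrel("D2", (5, 5), sq, 100.0),
            "D3": Barrel("D3", (5, 5), sq + 1.0, 100.0),
        }
        bm = BarrelMap(barrels=barrels)
        with pytest.raises(ValueError, match="multiple barrels"):
            wm.assign_columns(_rois([(6.0, 6.0)]), bm)


class TestReferenceFrame:
    def test_reference_centroid_maps_to_origin(self, barrel_map):
        c = barrel_map.centroid("D2")
        out = wm.to_reference_frame(np.array([c]), barrel_map, "D2")
        np.testing.assert_allclose(out[0], [0.0, 0.0], atol=1e-12)

    def test_vertical_row_axis_rotation(self):
        bm = wm.generate_barrel_map(wm.SynthParams())
        bm.row_axis_angle = np.pi / 2  # row axis points along +y
        c = bm.centroid("D2")
        out = wm.to_reference_frame(np.array([c + [0.0, 100.0]]), bm, "D2")
        np.testing.assert_allclose(out[0], [100.0, 0.0], atol=1e-9)

    def test_isometry(self, barrel_map):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 400, size=(40, 2))
        bm = wm.generate_barrel_map(wm.SynthParams())
        bm.row_axis_angle = 0.7
        out = wm.to_reference_frame(pts, bm, "C3")
        d_in = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        np.testing.assert_allclose(d_out, d_in, atol=1e-9)

    def test_missing_reference_error(self, barrel_map):
        bm = BarrelMap(barrels={"D2": barrel_map.barrels["D2"]})
        with pytest.raises(ValueError, match="C1"):
            wm.to_reference_frame(np.zeros((1, 2)), bm, "C1")


def _rf_frame(z_values, responsive=None, bw=None, ebw=None):
    n = len(z_values)
    df = pd.DataFrame({"roi_id": [f"r{i}" for i in range(n)]})
    for wk in wm.WHISKERS:
        df[f"z_{wk}"] = z_values
    df["is_responsive"] = True if responsive is None else responsive
    df["bw"] = bw if bw is not None else "D2"
    df["ebw_set"] = ebw if ebw is not None else [frozenset({"D2"})] * n
    return df


class TestPointRepresentation:
    def test_bin_arithmetic(self):
        rf = _rf_frame([1.0, 3.0])
        coords = np.array([[10.0, 0.0], [0.0, 60.0]])
        out = wm.point_representation(rf, coords, "D2")
        assert out["mean_z"].iloc[0] == pytest.approx(2.0)
        assert out["n"].iloc[0] == 2

    def test_half_open_edge(self):
        rf = _rf_frame([1.0])
        out = wm.point_representation(rf, np.array([[75.0, 0.0]]), "D2")
        assert out["n"].iloc[0] == 0
        assert out["n"].iloc[1] == 1
        assert np.isnan(out["mean_z"].iloc[0])


class TestNormalizedPolar:
    def test_examples(self, barrel_map):
        radius = wm.mean_barrel_radius(barrel_map)
        coords = np.array([[0.0, 0.0], [radius, 0.0], [2 * radius, 0.0]])
        out = wm.normalized_polar_coordinates(coords, barrel_map, "D2")
        assert out["radius_fraction"].iloc[0] == pytest.approx(0.0)
        assert out["radius_fraction"].iloc[1] == pytest.approx(1.0, rel=1e-6)
        assert out["angle_rad"].iloc[1] == pytest.approx(0.0)
        assert out["radius_fraction"].iloc[2] == pytest.approx(
            2 * out["radius_fraction"].iloc[1]
        )


class TestFractionTuned:
    def test_fraction_arithmetic(self):
        n = 58
        bw = ["D2"] * 31 + ["C1"] * 27
        rf = _rf_frame([1.0] * n, bw=bw, ebw=[frozenset({b}) for b in bw])
        coords = np.tile([[10.0, 0.0]], (n, 1))
        out = wm.fraction_tuned_by_distance(rf, coords, "D2", measure="BW")
        assert out["fraction"].iloc[0] == pytest.approx(31 / 58)
        assert out["tuned"].iloc[0] == 31 and out["n"].iloc[0] == 58

    def test_empty_bin_is_missing(self):
        rf = _rf_frame([1.0], bw=["D2"], ebw=[frozenset({"D2"})])
        out = wm.fraction_tuned_by_distance(
            rf, np.array([[100.0, 0.0]]), "D2", measure="BW"
        )
        assert np.isnan(out["fraction"].iloc[0])
        assert out["n"].iloc[0] == 0

    def test_ebw_superset_of_bw(self, small_analysis):
        rf, coords = small_analysis["rf"], small_analysis["coords"]
        # coords are in rois order == rf order for the synthetic session
        f_bw = wm.fraction_tuned_by_distance(rf, coords, "D2", measure="BW")
        f_ebw = wm.fraction_tuned_by_distance(rf, coords, "D2", measure="eBW")
        both = f_bw.merge(f_ebw, on="bin_lo_um", suffixes=("_bw", "_ebw"))
        ok = both["n_bw"] > 0
        assert (
            both.loc[ok, "fraction_ebw"] >= both.loc[ok, "fraction_bw"] - 1e-12
        ).all()


class TestCompareTunedFractions:
    def test_reported_contingency_tables(self):
        _, p = wm.compare_tuned_fractions(111, 135, 39, 58)
        assert p == pytest.approx(0.025, abs=0.0005)
        _, p = wm.compare_tuned_fractions(57, 63, 35, 48)
        assert p == pytest.approx(0.021, abs=0.0005)

    def test_identical_proportions(self):
        _, p = wm.compare_tuned_fractions(10, 20, 10, 20)
        assert p == pytest.approx(1.0)

    def test_zero_total_error(self):
        with pytest.raises(ValueError):
            wm.compare_tuned_fractions(0, 0, 1, 2)


class TestKmeansBins:
    def test_singleton_bins(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels, table = wm.kmeans_spatial_bins(pts, k=3, seed=0, values=[1.0, 2.0, 3.0])
        assert len(set(labels)) == 3
        assert sorted(table["mean_value"]) == [1.0, 2.0, 3.0]

    def test_two_clouds_match_bruteforce_partition(self):
        rng = np.random.default_rng(1)
        a = rng.normal((0, 0), 0.5, size=(5, 2))
        b = rng.normal((20, 20), 0.5, size=(5, 2))
        pts = np.vstack([a, b])
        labels, _ = wm.kmeans_spatial_bins(pts, k=2, seed=0)

        def within_ss(mask):
            tot = 0.0
            for sel in (mask, ~mask):
                if sel.sum():
                    c = pts[sel].mean(axis=0)
                    tot += ((pts[sel] - c) ** 2).sum()
            return tot

        best = min(
            (
                np.isin(np.arange(10), list(idx))
                for r in range(1, 10)
                for idx in itertools.combinations(range(10), r)
            ),
            key=within_ss,
        )
        got = labels == labels[0]
        assert np.array_equal(got, best) or np.array_equal(got, ~best)

    def test_determinism_and_validation(self):
        pts = np.random.default_rng(2).normal(size=(12, 2))
        l1, _ = wm.kmeans_spatial_bins(pts, k=4, seed=5)
        l2, _ = wm.kmeans_spatial_bins(pts, k=4, seed=5)
        np.testing.assert_array_equal(l1, l2)
        with pytest.raises(ValueError):
            wm.kmeans_spatial_bins(pts, k=0)
        with pytest.raises(ValueError):
            wm.kmeans_spatial_bins(pts, k=13)


class TestBarrelRadius:
    def test_inverse_formula(self):
        assert wm.barrel_radius_from_area(np.pi * 75.0**2) == pytest.approx(75.0)
        assert wm.barrel_radius_from_area(np.pi) == pytest.approx(1.0)

    def test_mean_radius(self):
        radii = wm.barrel_radius_from_area(np.array([np.pi, 4 * np.pi]))
        assert radii.mean() == pytest.approx(1.5)

    def test_nonpositive_area_error(self):
        with pytest.raises(ValueError):
            wm.barrel_radius_from_area(0.0)
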