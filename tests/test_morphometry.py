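"""Tests for point-cloud alignment, slicing and slice-trait measurement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import special_ortho_group

from winggrad import synthetic as syn
from winggrad.morphometry import (SliceTraits, WingScan, align_pointcloud,
                                  measure_slice, measure_wing, scale_by_mass,
                                  slice_wing, standardize_profiles,
                                  summarize_species, unscale_by_mass)


def box_cloud(lx=100.0, ly=40.0, lz=4.0, n=12):
    g = np.meshgrid(np.linspace(0, lx, 3 * n), np.linspace(0, ly, n),
                    np.linspace(0, lz, n), indexing="ij")
    return np.column_stack([a.ravel() for a in g])


def _match_up_to_sign(A, B):
    """Max per-coordinate discrepancy after the best per-axis sign flips."""
    best = np.inf
    for sx in (1, -1):
        for sy in (1, -1):
            for sz in (1, -1):
                d = np.abs(A - B * np.array([sx, sy, sz])).max()
                best = min(best, d)
    return best


class TestAlignment:
    def test_identity_on_convention_cloud(self):
        pts = box_cloud()
        aligned = align_pointcloud(pts)
        centered = pts - pts.mean(axis=0)
        assert _match_up_to_sign(aligned, centered) < 1e-9

    def test_rotation_about_z_recovered(self):
        pts = box_cloud()
        theta = np.pi / 2
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        aligned = align_pointcloud(pts @ R.T)
        centered = pts - pts.mean(axis=0)
        assert _match_up_to_sign(aligned, centered) < 1e-9

    def test_collinear_cloud_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 50), np.zeros(50), np.zeros(50)])
        with pytest.raises(ValueError, match="collinear"):
            align_pointcloud(line)

    def test_random_rotation_of_wing_recovers_chords(self):
        """A rotated synthetic wing realigns so per-slice chords match the
        unrotated ground truth within 1%."""
        scan, geom = syn.simulate_wing_pointcloud(n_points=30000, seed=1)
        R = special_ortho_group.rvs(3, random_state=1)
        rotated = scan.points @ R.T + np.array([12.0, -7.0, 3.0])
        aligned = align_pointcloud(rotated)
        x0 = scan.points[:, 0] - scan.points[:, 0].mean()
        for frac in (0.2, 0.5, 0.8):
            lo = x0.min() + frac * (x0.max() - x0.min())
            sel_o = (x0 >= lo) & (x0 < lo + 10)
            sel_a = (aligned[:, 0] >= lo) & (aligned[:, 0] < lo + 10)
            c_o = np.ptp(scan.points[sel_o, 1])
            c_a = np.ptp(aligned[sel_a, 1])
            assert abs(c_a / c_o - 1.0) < 0.01

    @settings(max_examples=5, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_motion_invariance(self, seed):
        """Traits are invariant (1e-6 relative) to rotation + translation."""
        scan, _ = syn.simulate_wing_pointcloud(n_points=8000, seed=99)
        rng = np.random.default_rng(seed)
        R = special_ortho_group.rvs(3, random_state=seed)
        moved = scan.points @ R.T + rng.uniform(-50, 50, 3)
        a0 = align_pointcloud(scan.points)
        a1 = align_pointcloud(moved)
        assert np.abs(a1 - a0).max() < 1e-6 * np.abs(a0).max()


class TestSlicing:
    def flat_plate(self):
        # grid with exact X bounds [0, 350] so the bin arithmetic is exact
        g = np.meshgrid(np.linspace(0, 350, 351), np.linspace(0, 40, 12),
                        np.linspace(0, 2, 5), indexing="ij")
        return np.column_stack([a.ravel() for a in g])

    def test_flat_plate_bin_arithmetic(self):
        scan = WingScan(points=self.flat_plate(), species_id="sp", body_mass=100.0,
                        wrist_x=100.0)
        slices = slice_wing(scan)
        hw = [s for s in slices if s.region == "HW"]
        prox = [s for s in slices if s.region in ("AW", "WRIST")]
        assert len(hw) == 25
        assert len(prox) == 10
        assert hw[0].x_hi - hw[0].x_lo == pytest.approx(10.0)
        assert sum(s.region == "WRIST" for s in slices) == 1

    def test_narrow_handwing(self):
        pts = self.flat_plate()
        scan = WingScan(points=pts, species_id="sp", body_mass=100.0,
                        wrist_x=float(pts[:, 0].max()) - 25.0)
        slices = slice_wing(scan)
        hw = [s for s in slices if s.region == "HW"]
        assert len(hw) == 25
        assert hw[0].x_hi - hw[0].x_lo == pytest.approx(1.0, rel=1e-9)

    def test_aw_bin_count_matches_geometry(self):
        scan, geom = syn.simulate_wing_pointcloud(n_points=20000, seed=2)
        slices = slice_wing(scan)
        w = (scan.points[:, 0].max() - geom.wrist_x) / 25
        expected = int(np.floor((geom.wrist_x - scan.points[:, 0].min()) / w))
        prox = [s for s in slices if s.slice_index < 0]
        assert len(prox) == expected

    def test_wrist_beyond_tip_error(self):
        pts = self.flat_plate()
        with pytest.raises(ValueError):
            scan = WingScan(points=pts, species_id="s", body_mass=1.0,
                            wrist_x=350.0)
            slice_wing(scan)

    def test_sparse_hw_bin_warns(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(0, 100, 100), rng.uniform(0, 10, 100),
                               rng.uniform(0, 1, 100)])
        scan = WingScan(points=pts, species_id="s", body_mass=1.0, wrist_x=50.0)
        with pytest.warns(UserWarning):
            slice_wing(scan)


class TestMeasureSlice:
    def test_rectangle_closed_form(self):
        g = np.meshgrid(np.linspace(0, 40, 400), np.linspace(0, 2, 60),
                        indexing="ij")
        pts = np.column_stack([np.zeros(g[0].size), g[0].ravel(), g[1].ravel()])
        t = measure_slice(pts)
        assert t.chord == pytest.approx(40.0)
        assert t.xst == pytest.approx(2.0, rel=0.02)
        assert t.camber == pytest.approx(0.05)
        assert t.xsa == pytest.approx(80.0, rel=0.02)

    def test_circular_arc_camber(self):
        # zero-thickness cambered plate, chord 40, rise 4: camber = 0.1
        y = np.linspace(0, 40, 4000)
        z = 4.0 * (1 - (2 * y / 40 - 1) ** 2)
        pts = np.column_stack([np.zeros_like(y), y, z])
        t = measure_slice(pts)
        assert t.camber == pytest.approx(0.1, rel=1e-6)

    def test_convex_polygon_area_vs_shoelace(self):
        rng = np.random.default_rng(3)
        from scipy.spatial import ConvexHull

        raw = rng.uniform(0, 1, (12, 2)) * np.array([40.0, 6.0])
        hull = ConvexHull(raw)
        verts = raw[hull.vertices]
        shoelace = hull.volume  # 2-D hull: volume is the area
        from shapely import Point, Polygon

        poly = Polygon(verts)
        pts = []
        while len(pts) < 20000:
            cand = rng.uniform([0, 0], [40.0, 6.0], (4000, 2))
            pts.extend(c for c in cand if poly.contains(Point(c)))
        yz = np.asarray(pts[:20000])
        pts3 = np.column_stack([np.zeros(len(yz)), yz])
        t = measure_slice(pts3)
        assert t.xsa == pytest.approx(shoelace, rel=0.02)

    def test_zero_chord_error(self):
        pts = np.column_stack([np.zeros(20), np.zeros(20), np.linspace(0, 1, 20)])
        with pytest.raises(ValueError, match="chord"):
            measure_slice(pts)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            measure_slice(np.zeros((5, 3)))

    def test_scale_covariance(self):
        scan, _ = syn.simulate_wing_pointcloud(n_points=20000, seed=4)
        slices = slice_wing(scan)
        s = slices[len(slices) // 2]
        t1 = measure_slice(s.points)
        t2 = measure_slice(3.0 * s.points)
        assert t2.chord == pytest.approx(3.0 * t1.chord, rel=1e-9)
        assert t2.xst == pytest.approx(3.0 * t1.xst, rel=1e-9)
        assert t2.xsa == pytest.approx(9.0 * t1.xsa, rel=1e-9)
        assert t2.camber == pytest.approx(t1.camber, rel=1e-9)


class TestParameterRecovery:
    def test_slice_traits_recover_geometry(self, bench_wing):
        """On a dense parametric wing every slice's chord, camber and XST
        land within 2% — and XSA within 5% — of the generating surface."""
        scan, geom = bench_wing
        for s in slice_wing(scan):
            if len(s.points) < 500:
                continue
            t = measure_slice(s.points, s.slice_index, s.region)
            truth = geom.slice_truth(s.x_lo, s.x_hi)
            assert abs(t.chord / truth["chord"] - 1) < 0.02
            assert abs(t.camber / truth["camber"] - 1) < 0.02
            assert abs(t.xst / truth["xst"] - 1) < 0.02
            assert abs(t.xsa / truth["xsa"] - 1) < 0.05


class TestMassScaling:
    def test_closed_forms(self):
        t = SliceTraits(1, "HW", camber=0.08, chord=20.0, xst=1.0, xsa=50.0)
        s = scale_by_mass(t, 1000.0)
        assert s.chord == pytest.approx(2.0)
        assert s.xsa == pytest.approx(0.5)
        assert s.camber == 0.08
        assert s.scaled

    def test_round_trip_exact(self):
        t = SliceTraits(3, "AW", camber=0.1, chord=33.3, xst=2.2, xsa=47.1)
        back = unscale_by_mass(scale_by_mass(t, 123.4), 123.4)
        for f in ("camber", "chord", "xst", "xsa"):
            assert getattr(back, f) == pytest.approx(getattr(t, f), rel=1e-12)

    def test_bad_mass(self):
        t = SliceTraits(1, "HW", 0.1, 10.0, 1.0, 5.0)
        with pytest.raises(ValueError):
            scale_by_mass(t, 0.0)


def _specimen_table(specimen, species, values_by_slice):
    return pd.DataFrame([
        {"specimen": specimen, "species": species, "slice_index": idx,
         "region": "HW" if idx > 0 else ("WRIST" if idx == -1 else "AW"),
         "camber": v, "chord": v + 1, "xst": v + 2, "xsa": v + 3, "n_points": 100}
        for idx, v in values_by_slice.items()])


class TestSpeciesSummaries:
    def test_single_specimen_identity(self):
        tab = _specimen_table("a1", "spA", {1: 0.5, 2: 0.6})
        med = summarize_species(tab)
        assert med.loc[("spA", 1), "camber"] == 0.5
        assert med.loc[("spA", 2), "chord"] == 1.6

    def test_odd_median(self):
        tabs = pd.concat([_specimen_table(f"a{i}", "spA", {1: v})
                          for i, v in enumerate([1.0, 2.0, 10.0])])
        med = summarize_species(tabs)
        assert med.loc[("spA", 1), "camber"] == 2.0

    def test_noisy_cohort_median_near_truth(self):
        rng = np.random.default_rng(4)
        truth, sd = 0.12, 0.01
        tabs = pd.concat([
            _specimen_table(f"a{i}", "spA", {1: truth + rng.normal(0, sd)})
            for i in range(6)])
        med = summarize_species(tabs)
        assert abs(med.loc[("spA", 1), "camber"] - truth) < 3 * sd / np.sqrt(6)


class TestStandardize:
    def _species_table(self, n_species=3, prox=13, value=1.0):
        tabs = []
        for k in range(n_species):
            vals = {i: value for i in range(-prox, 0)}
            vals.update({i: value for i in range(1, 26)})
            tabs.append(_specimen_table(f"a{k}", f"sp{k}", vals))
        return summarize_species(pd.concat(tabs))

    def test_truncates_to_35_columns(self):
        profiles = standardize_profiles(self._species_table(prox=13))
        for prof in profiles.values():
            assert prof.values.shape[1] == 35
            assert prof.regions.count("AW") == 10
            assert prof.regions.count("HW") == 25

    def test_wrist_included_mode(self):
        profiles = standardize_profiles(self._species_table(), include_wrist=True)
        prof = profiles["camber"]
        assert prof.values.shape[1] == 36
        assert prof.regions.count("WRIST") == 1

    def test_all_ones_log10_is_zero(self):
        profiles = standardize_profiles(self._species_table(value=1.0), log10=True)
        assert np.allclose(profiles["camber"].values.to_numpy(), 0.0)

    def test_species_with_short_armwing_excluded(self):
        short = _specimen_table("b0", "spShort",
                                {**{i: 1.0 for i in range(-5, 0)},
                                 **{i: 1.0 for i in range(1, 26)}})
        tabs = []
        for k in range(2):
            vals = {i: 1.0 for i in list(range(-13, 0)) + list(range(1, 26))}
            tabs.append(_specimen_table(f"a{k}", f"sp{k}", vals))
        tabs.append(short)
        med = summarize_species(pd.concat(tabs))
        with pytest.warns(UserWarning, match="spShort"):
            profiles = standardize_profiles(med)
        assert "spShort" not in profiles["camber"].values.index


class TestMeasureWing:
    def test_full_wing_table(self):
        scan, _ = syn.simulate_wing_pointcloud(n_points=25000, seed=5)
        df = measure_wing(scan, scale=True)
        assert set(df["region"]) == {"AW", "WRIST", "HW"}
        assert (df["slice_index"] > 0).sum() == 25
        hw = df[df.slice_index > 0]
        assert hw[["camber", "chord", "xst", "xsa"]].notna().all().all()
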