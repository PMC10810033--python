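"""Geometry extraction: polygon moments, composition, slicing, orientation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platefatigue import mesh_geometry as mg
from platefatigue import synthetic_plates as sp
from platefatigue.errors import (
    GeometryError,
    MeshFormatError,
    OrientationWarning,
)

from conftest import mc_polygon_moments


def _rect(w, h, cx=0.0, cy=0.0):
    return mg.SectionPolyline(np.array([
        [cx - w / 2, cy - h / 2], [cx + w / 2, cy - h / 2],
        [cx + w / 2, cy + h / 2], [cx - w / 2, cy + h / 2],
    ]))


class TestPolygonMoments:
    @pytest.mark.parametrize(
        "vertices, area, centroid, ixx",
        [
            ([(0, 0), (1, 0), (1, 1), (0, 1)], 1.0, (0.5, 0.5), 1 / 12),
            ([(-5, -1.5), (5, -1.5), (5, 1.5), (-5, 1.5)], 30.0, (0, 0), 22.5),
            # right triangle b=3 h=2: Ixx about centroid = b h^3/36
            ([(0, 0), (3, 0), (0, 2)], 3.0, (1.0, 2 / 3), 3 * 8 / 36),
        ],
    )
    def test_closed_forms(self, vertices, area, centroid, ixx):
        a, c, i = mg.polygon_moments(mg.SectionPolyline(np.array(vertices, float)))
        assert a == pytest.approx(area, rel=1e-12)
        assert c == pytest.approx(centroid, abs=1e-12)
        assert i == pytest.approx(ixx, rel=1e-12)

    def test_winding_normalized(self):
        cw = mg.SectionPolyline(np.array([(0, 0), (0, 1), (1, 1), (1, 0)], float))
        a, _, i = mg.polygon_moments(cw)
        assert a == pytest.approx(1.0)
        assert i == pytest.approx(1 / 12)

    def test_monte_carlo_oracle(self):
        """Closed forms agree with a seeded point-in-polygon integration."""
        rng = np.random.default_rng(7)
        pts = rng.uniform(-4, 4, size=(12, 2))
        # convex hull ordering gives a guaranteed-simple polygon
        from scipy.spatial import ConvexHull

        hull = pts[ConvexHull(pts).vertices]
        a, c, i = mg.polygon_moments(mg.SectionPolyline(hull))
        a_mc, c_mc, i_mc = mc_polygon_moments(hull)
        assert a == pytest.approx(a_mc, rel=5e-3)
        assert c[1] == pytest.approx(c_mc[1], abs=5e-3 * 8)
        assert i == pytest.approx(i_mc, rel=5e-3)

    def test_self_intersecting_rejected(self):
        bowtie = mg.SectionPolyline(np.array([(0, 0), (1, 1), (1, 0), (0, 1)], float))
        with pytest.raises(GeometryError):
            mg.polygon_moments(bowtie)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(GeometryError):
            mg.SectionPolyline(np.array([(0, 0), (1, 0)], float))

    @settings(derandomize=True, max_examples=30)
    @given(dx=st.floats(-100, 100), dy=st.floats(-100, 100))
    def test_ixx_translation_invariant(self, dx, dy):
        base = np.array([(0, 0), (4, 0), (5, 2), (1, 3)], float)
        _, _, i0 = mg.polygon_moments(mg.SectionPolyline(base))
        _, _, i1 = mg.polygon_moments(mg.SectionPolyline(base + [dx, dy]))
        assert i1 == pytest.approx(i0, rel=1e-9, abs=1e-9)


class TestCompositeProperties:
    def test_slotted_rectangle(self):
        """10 x 3 section with a 4 mm central slot: Ixx = (10-4) 3^3/12."""
        left = _rect(3, 3, cx=-3.5)
        right = _rect(3, 3, cx=3.5)
        props = mg.composite_properties([left, right], station=1.0)
        assert props.area == pytest.approx(18.0)
        assert props.centroid[0] == pytest.approx(0.0, abs=1e-12)
        assert props.Ixx == pytest.approx(13.5)
        assert props.d == pytest.approx(4.0)
        assert props.w == pytest.approx(10.0)
        assert props.t == pytest.approx(3.0)
        assert props.n_polylines == 2

    def test_single_polyline_passthrough(self):
        props = mg.composite_properties([_rect(10, 3)], station=0.0)
        assert props.Ixx == pytest.approx(22.5)
        assert props.d == 0.0
        assert props.n_polylines == 1

    def test_equal_area_centroid_midpoint(self):
        a = _rect(2, 2, cx=-3, cy=1)
        b = _rect(2, 2, cx=3, cy=-1)
        props = mg.composite_properties([a, b], station=0.0)
        assert props.centroid == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_parallel_axis_additivity_against_monte_carlo(self):
        """Composite Ixx equals the sum of parallel-axis contributions."""
        a = _rect(4, 2, cx=-3, cy=0.5)
        b = _rect(2, 3, cx=3, cy=-0.5)
        props = mg.composite_properties([a, b], station=0.0)
        total, ssum = 0.0, 0.0
        for poly in (a, b):
            area, (cx, cy), _ = mg.polygon_moments(poly)
            a_mc, c_mc, i_mc = mc_polygon_moments(poly.vertices, 400_000, seed=3)
            ssum += i_mc + a_mc * (c_mc[1] - props.centroid[1]) ** 2
            total += a_mc
        assert props.Ixx == pytest.approx(ssum, rel=5e-3)
        assert props.area == pytest.approx(total, rel=5e-3)

    def test_zero_polylines_rejected(self):
        with pytest.raises(GeometryError):
            mg.composite_properties([], station=0.0)


class TestCriticalSection:
    def _props(self, ixx, z):
        return mg.SectionProperties(station_z=z, area=1.0, centroid=(0, 0),
                                    Ixx=ixx, w=10, t=3, d=0)

    def test_minimum_selected(self):
        secs = [self._props(5, 0), self._props(3, 1), self._props(4, 2)]
        idx, crit = mg.critical_section(secs)
        assert idx == 1 and crit.Ixx == 3

    def test_tie_broken_by_station(self):
        secs = [self._props(3, 5.0), self._props(3, 1.0)]
        idx, _ = mg.critical_section(secs)
        assert idx == 1

    def test_uniform_bar_first_index(self):
        secs = [self._props(3, z) for z in range(4)]
        idx, _ = mg.critical_section(secs)
        assert idx == 0

    def test_larger_hole_wins(self):
        """Two holes, same w,t: the larger d gives the smaller Ixx."""
        p = sp.SyntheticPlateParams(length=120, width=10, thickness=3,
                                    holes=[(-20.0, 3.0), (20.0, 5.0)])
        small = sp.analytic_properties(p, -20.0)
        large = sp.analytic_properties(p, 20.0)
        idx, crit = mg.critical_section([small, large])
        assert crit.station_z == 20.0 and crit.d == 5.0

    def test_empty_rejected(self):
        with pytest.raises(GeometryError):
            mg.critical_section([])


class TestLoadAndOrient:
    def test_stl_round_trip_counts(self, plain_mesh, tmp_path):
        path = tmp_path / "plate.stl"
        sp.write_stl(plain_mesh, path)
        loaded = mg.load_mesh(path)
        assert len(loaded.vertices) == len(plain_mesh.vertices)
        assert len(loaded.faces) == len(plain_mesh.faces)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.stl"
        path.touch()
        with pytest.raises(MeshFormatError):
            mg.load_mesh(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(MeshFormatError):
            mg.load_mesh(tmp_path / "nope.stl")

    def test_ascii_binary_equivalence(self, holed_mesh, holed_params, tmp_path):
        """Same plate as ASCII and binary STL gives the same sections.

        Binary STL stores float32 coordinates by format definition, so
        agreement is bounded by single precision, not double.
        """
        pb, pa = tmp_path / "b.stl", tmp_path / "a.stl"
        sp.write_stl(holed_mesh, pb)
        sp.write_stl(holed_mesh, pa, ascii_format=True)
        cfg = mg.SlicingConfig(n_planes=21)
        sb = mg.extract_sections(mg.load_mesh(pb), cfg)
        sa = mg.extract_sections(mg.load_mesh(pa), cfg)
        assert len(sb) == len(sa)
        for x, y in zip(sb, sa):
            assert x.Ixx == pytest.approx(y.Ixx, rel=1e-5)
            assert x.area == pytest.approx(y.area, rel=1e-5)
            assert x.d == pytest.approx(y.d, abs=1e-4)

    def test_aligned_plate_identity(self, plain_mesh):
        _, transform = mg.orient_plate(plain_mesh)
        assert np.allclose(transform, np.eye(4), atol=1e-9)

    def test_rotation_recovered(self, plain_mesh):
        theta = np.pi / 2
        rot = np.array([[1, 0, 0],
                        [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        moved = mg.TriMesh(vertices=plain_mesh.vertices @ rot.T + [4.0, -2.0, 9.0],
                           faces=plain_mesh.faces)
        oriented, _ = mg.orient_plate(moved)
        reference, _ = mg.orient_plate(plain_mesh)
        assert np.allclose(np.sort(oriented.extents), np.sort(reference.extents),
                           atol=1e-6)
        assert oriented.extents[2] == pytest.approx(reference.extents[2], abs=1e-6)

    def test_near_cube_warns(self):
        cube = sp.generate_plate_mesh(
            sp.SyntheticPlateParams(length=10.2, width=10.1, thickness=10.0,
                                    mesh_resolution=3.0))
        with pytest.warns(OrientationWarning):
            oriented, _ = mg.orient_plate(cube)
        assert oriented.extents[2] == pytest.approx(10.2)

    def test_rigid_motion_invariance(self, holed_mesh, holed_params):
        """A translated + rotated copy yields the same critical section."""
        theta = np.pi / 2
        rot = np.array([[np.cos(theta), 0, np.sin(theta)],
                        [0, 1, 0],
                        [-np.sin(theta), 0, np.cos(theta)]])
        moved = mg.TriMesh(vertices=holed_mesh.vertices @ rot.T + [11.0, -4.0, 2.5],
                           faces=holed_mesh.faces)
        cfg = mg.SlicingConfig(n_planes=41)
        _, c0 = mg.critical_section(mg.extract_sections(holed_mesh, cfg))
        _, c1 = mg.critical_section(mg.extract_sections(moved, cfg))
        for attr in ("area", "Ixx", "w", "t", "d"):
            assert getattr(c1, attr) == pytest.approx(getattr(c0, attr), rel=1e-6)


class TestSlicing:
    def test_minimal_two_planes(self, plain_mesh):
        cfg = mg.SlicingConfig(n_planes=2, two_pass=False)
        result = mg.slice_plate(plain_mesh, cfg)
        assert len(result) == 2
        assert all(len(polys) == 1 for _, polys in result)

    def test_hole_station_count(self, holed_mesh, holed_params):
        """Stations inside the hole (and only those) report two polylines."""
        cfg = mg.SlicingConfig(n_planes=41)
        sections = mg.extract_sections(holed_mesh, cfg)
        spacing = 50.0 / 40  # central 50% of a 100 mm plate, 41 planes
        n_two = sum(1 for s in sections if s.n_polylines == 2)
        expected = sum(
            1 for s in sections
            if abs(s.station_z) < 2.0 - 1e-9  # hole radius
        )
        assert n_two == expected
        assert n_two == pytest.approx(4.0 / spacing, abs=1.5)
        assert all(s.n_polylines == 1 for s in sections
                   if abs(s.station_z) > 2.0 + spacing)

    def test_curved_two_pass_recovers_normal_area(self):
        """Inclined pass-1 cuts inflate the area; pass 2 follows the axis."""
        p = sp.SyntheticPlateParams(length=100, width=10, thickness=3,
                                    curvature_radius=200, mesh_resolution=0.8)
        mesh = sp.generate_plate_mesh(p)
        oriented, _ = mg.orient_plate(mesh)
        cfg1 = mg.SlicingConfig(n_planes=41, two_pass=False)
        cfg2 = mg.SlicingConfig(n_planes=41, two_pass=True)
        areas1 = [mg.composite_properties(polys, z).area
                  for z, polys in mg.slice_plate(oriented, cfg1)]
        areas2 = [mg.composite_properties(polys, z).area
                  for z, polys in mg.slice_plate(oriented, cfg2)]
        true_area = 30.0
        # pass 2 within 1% everywhere
        assert np.allclose(areas2, true_area, rtol=1e-2)
        # pass 1 inflated by ~1/cos(tilt) at the region ends (tilt = 25/200)
        inflation = max(areas1) / true_area
        assert inflation == pytest.approx(1.0 / np.cos(25.0 / 200.0), rel=5e-3)

    def test_refinement_convergence(self, holed_mesh):
        c100, _ = mg.critical_from_mesh(holed_mesh, mg.SlicingConfig(n_planes=100))
        c400, _ = mg.critical_from_mesh(holed_mesh, mg.SlicingConfig(n_planes=400))
        assert abs(c100.Ixx - c400.Ixx) / c400.Ixx < 0.005

    def test_critical_near_hole_center(self, holed_mesh, holed_params):
        cfg = mg.SlicingConfig(n_planes=100)
        sections = mg.extract_sections(holed_mesh, cfg)
        _, crit = mg.critical_section(sections)
        spacing = 50.0 / 99
        assert abs(crit.station_z - 0.0) <= spacing
        refined, _ = mg.critical_from_mesh(holed_mesh, cfg)
        assert abs(refined.station_z) < spacing / 4
        assert refined.Ixx <= crit.Ixx
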