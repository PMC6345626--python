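"""Lattice generators, trimming, porosity and mesh export."""

import json
import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

from scaffold_regen.designs import DESIGNS, POLYAMIDE
from scaffold_regen.lattice import (Box, CalibrationError, Cylinder,
                                    DegenerateDomainError, Lattice,
                                    PackingError, export_mesh, generate_cubic,
                                    generate_octetruss, generate_stochastic,
                                    grade_thickness, porosity,
                                    solve_radius_for_porosity,
                                    trim_to_cylinder)


def octet_cell_edges_oracle(a: float) -> set:
    """Independent enumeration of the octet-truss edges of one cell:
    FCC sites (8 corners + 6 face centers), edges between sites at the
    nearest-neighbour distance a/sqrt(2)."""
    corners = [(i * a, j * a, k * a) for i in (0, 1) for j in (0, 1)
               for k in (0, 1)]
    faces = [(a / 2, a / 2, 0), (a / 2, a / 2, a),
             (a / 2, 0, a / 2), (a / 2, a, a / 2),
             (0, a / 2, a / 2), (a, a / 2, a / 2)]
    pts = corners + faces
    edges = set()
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = np.linalg.norm(np.subtract(pts[i], pts[j]))
            if abs(d - a / np.sqrt(2)) < 1e-9:
                key = tuple(sorted([tuple(np.round(pts[i], 6)),
                                    tuple(np.round(pts[j], 6))]))
                edges.add(key)
    return edges


class TestOctetruss:
    def test_single_cell_matches_enumeration_oracle(self, test_material):
        lat = generate_octetruss(np.array([1.0, 1.0, 1.0]), 1.0, 0.05,
                                 test_material)
        got = set()
        for i, j in lat.struts:
            key = tuple(sorted([tuple(np.round(lat.nodes[i], 6)),
                                tuple(np.round(lat.nodes[j], 6))]))
            got.add(key)
        assert got == octet_cell_edges_oracle(1.0)
        assert lat.n_struts == 36

    def test_all_struts_have_fcc_neighbour_length(self, test_material):
        lat = generate_octetruss(np.array([3.0, 3.0, 3.0]), 1.5, 0.05,
                                 test_material)
        np.testing.assert_allclose(lat.strut_lengths(), 1.5 / np.sqrt(2),
                                   rtol=1e-9)

    def test_bbox_growth_is_monotone(self, test_material):
        small = generate_octetruss(np.array([2.0, 2.0, 2.0]), 1.0, 0.05,
                                   test_material)
        big = generate_octetruss(np.array([4.0, 2.0, 2.0]), 1.0, 0.05,
                                 test_material)
        assert big.n_struts > small.n_struts
        small_nodes = {tuple(np.round(p, 6)) for p in small.nodes}
        big_nodes = {tuple(np.round(p, 6)) for p in big.nodes}
        assert small_nodes <= big_nodes

    def test_degenerate_bbox_raises(self, test_material):
        with pytest.raises(DegenerateDomainError):
            generate_octetruss(np.array([0.5, 2.0, 2.0]), 1.0, 0.05,
                               test_material)


class TestCubic:
    @pytest.mark.parametrize("n,nodes,struts", [(1, 8, 12), (2, 27, 54)])
    def test_grid_counts(self, n, nodes, struts, test_material):
        lat = generate_cubic(np.array([float(n)] * 3), 1.0, 0.05,
                             test_material)
        assert (lat.n_nodes, lat.n_struts) == (nodes, struts)

    def test_struts_axis_aligned(self, test_material):
        lat = generate_cubic(np.array([3.0, 2.0, 2.0]), 1.0, 0.05,
                             test_material)
        vec = np.abs(lat.strut_vectors())
        # exactly one nonzero component per strut
        assert np.all((vec > 1e-12).sum(axis=1) == 1)


class TestStochastic:
    def test_mean_degree_hits_target(self, test_material):
        lat = generate_stochastic(np.array([10.0, 10.0, 10.0]), 400,
                                  4.5, seed=0, material=test_material)
        assert 4.4 <= lat.mean_degree() <= 4.6
        assert lat.n_components() == 1

    def test_poisson_disk_minimum_distance(self, test_material):
        lat = generate_stochastic(np.array([10.0, 10.0, 10.0]), 300,
                                  4.5, seed=1, material=test_material)
        d, _ = cKDTree(lat.nodes).query(lat.nodes, k=2)
        volume = 1000.0
        r_min = (0.2 * 6.0 * volume / (np.pi * 300)) ** (1 / 3)
        assert d[:, 1].min() >= r_min * (1 - 1e-9)

    def test_same_seed_is_bit_identical(self, test_material):
        a = generate_stochastic(np.array([8.0] * 3), 200, 4.5, seed=3,
                                material=test_material)
        b = generate_stochastic(np.array([8.0] * 3), 200, 4.5, seed=3,
                                material=test_material)
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.struts, b.struts)

    def test_infeasible_connectivity_raises(self, test_material):
        with pytest.raises(PackingError):
            generate_stochastic(np.array([5.0] * 3), 27, 26.0, seed=0,
                                material=test_material)


class TestTrim:
    def test_enclosing_cylinder_keeps_everything(self, test_material):
        lat = generate_cubic(np.array([2.0] * 3), 1.0, 0.05, test_material)
        lat = lat.translated(-lat.bbox().mean(axis=0))
        out = trim_to_cylinder(lat, 10.0, 10.0)
        assert out.n_struts == lat.n_struts
        assert out.total_strut_length() == pytest.approx(
            lat.total_strut_length())

    def test_trim_shortens_and_is_idempotent(self, test_material):
        lat = generate_octetruss(np.array([4.0] * 3), 1.0, 0.05,
                                 test_material)
        lat = lat.translated(-lat.bbox().mean(axis=0))
        once = trim_to_cylinder(lat, 3.0, 3.0)
        assert once.total_strut_length() < lat.total_strut_length()
        twice = trim_to_cylinder(once, 3.0, 3.0)
        assert twice.n_struts == once.n_struts
        assert twice.total_strut_length() == pytest.approx(
            once.total_strut_length(), rel=1e-9)

    def test_disjoint_cylinder_raises(self, test_material):
        lat = generate_cubic(np.array([2.0] * 3), 1.0, 0.05, test_material)
        with pytest.raises(DegenerateDomainError):
            trim_to_cylinder(lat, 1.0, 1.0, center=(50.0, 50.0, 50.0))


class TestPorosity:
    def test_empty_lattice_is_fully_porous(self, test_material):
        lat = Lattice(np.zeros((0, 3)), np.zeros((0, 2), int),
                      np.zeros(0), test_material)
        assert porosity(lat, Box((0, 0, 0), (1, 1, 1))) == 1.0

    def test_single_axial_strut_analytic(self, test_material):
        lat = Lattice(np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 1.0]]),
                      np.array([[0, 1]]), np.array([0.1]), test_material)
        p = porosity(lat, Box((0, 0, 0), (1, 1, 1)), mode="analytic")
        assert p == pytest.approx(1.0 - np.pi * 0.01, abs=1e-9)

    def test_voxel_converges_to_analytic(self, test_material):
        # slender struts: the junction correction is negligible and the
        # voxel estimate should approach the analytic volume as h -> 0
        lat = generate_cubic(np.array([3.0] * 3), 1.0, 0.05, test_material)
        # margin keeps boundary struts wholly inside the domain
        dom = Box((-0.5, -0.5, -0.5), (3.5, 3.5, 3.5))
        ana = porosity(lat, dom, mode="analytic")
        errs = [abs(porosity(lat, dom, mode="voxel", voxel_size=h) - ana)
                for h in (0.05, 0.025)]
        assert errs[1] <= 0.01
        assert errs[1] <= errs[0] + 1e-4

    def test_porosity_decreases_with_radius(self, test_material):
        lat = generate_cubic(np.array([2.0] * 3), 1.0, 0.05, test_material)
        dom = Box((0.0, 0.0, 0.0), (2.0, 2.0, 2.0))
        values = [porosity(lat.with_radii(r), dom, mode="voxel",
                           voxel_size=0.05) for r in (0.05, 0.1, 0.2, 0.3)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestRadiusSolve:
    def test_pb_round_trip(self):
        r = solve_radius_for_porosity(DESIGNS["PB"])
        from scaffold_regen.lattice import build_design
        lat = build_design(DESIGNS["PB"], radius=r)
        cyl = Cylinder(16.0, 15.0)
        p = porosity(lat, cyl, mode="voxel", voxel_size=0.05)
        assert abs(p - 0.45) < 0.002 + 1e-9


class TestGradeThickness:
    def test_fixed_point_and_doubling(self, test_material):
        from scaffold_regen.mechanics import apparent_modulus

        lat = generate_cubic(np.array([3.0] * 3), 1.0, 0.08, test_material)
        e0 = apparent_modulus(lat, [0, 0, 1])
        same = grade_thickness(lat, e0)
        np.testing.assert_allclose(same.radii, lat.radii, rtol=1e-12)
        doubled = grade_thickness(lat, 2 * e0)
        e2 = apparent_modulus(doubled, [0, 0, 1])
        assert e2 == pytest.approx(2 * e0, rel=0.01)

    def test_stochastic_graded_to_trabecular_modulus(self, test_material):
        # grade a desk-scale stochastic block to the 1400 MPa trabecular
        # target within the 1% contract
        from scaffold_regen.designs import TITANIUM
        from scaffold_regen.mechanics import apparent_modulus

        lat = generate_stochastic(np.array([8.0] * 3), 350, 4.5, seed=2,
                                  material=TITANIUM, radius=0.25)
        graded = grade_thickness(lat, 1400.0)
        e = apparent_modulus(graded, [0, 0, 1])
        assert e == pytest.approx(1400.0, rel=0.01)

    def test_unreachable_target_raises(self, test_material):
        lat = generate_cubic(np.array([2.0] * 3), 1.0, 0.05, test_material)
        with pytest.raises(CalibrationError):
            grade_thickness(lat, 1e12)


class TestExport:
    def test_empty_lattice_raises(self, tmp_path, test_material):
        lat = Lattice(np.zeros((0, 3)), np.zeros((0, 2), int),
                      np.zeros(0), test_material)
        with pytest.raises(ValueError):
            export_mesh(lat, tmp_path / "empty.stl")

    def test_single_strut_tessellation_and_sidecar(self, tmp_path,
                                                   test_material):
        import trimesh

        lat = Lattice(np.array([[0, 0, 0], [0, 0, 5.0]]),
                      np.array([[0, 1]]), np.array([0.3]), test_material)
        path = export_mesh(lat, tmp_path / "one.stl", sections=16)
        mesh = trimesh.load(path)
        # capped cylinder: 2 * sections + 2 vertices
        assert len(mesh.vertices) == 2 * 16 + 2
        norms = np.linalg.norm(mesh.face_normals, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)
        sidecar = json.loads((tmp_path / "one.stl.json").read_text())
        assert sidecar["n_struts"] == 1
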