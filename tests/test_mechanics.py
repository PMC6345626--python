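"""Frame solver closed forms, invariances, sweeps and hysteresis fits."""

import numpy as np
import pytest

from scaffold_regen.designs import Material
from scaffold_regen.lattice import Lattice, generate_cubic
from scaffold_regen.mechanics import (DirectionSweep, SingularityError,
                                      WindowError, anisotropy_coefficient,
                                      apparent_modulus,
                                      direction_average_modulus,
                                      direction_sweep, frame_solve,
                                      frame_stiffness, _kappa,
                                      modulus_from_hysteresis,
                                      synthetic_hysteresis_curve)

MAT = Material("solid", elastic_modulus=2000.0, poisson_ratio=0.3)


def single_strut(length=10.0, radius=None):
    radius = radius if radius is not None else np.sqrt(1 / np.pi)  # A = 1
    return Lattice(np.array([[0, 0, 0], [0, 0, length]]),
                   np.array([[0, 1]]), np.array([radius]), MAT)


class TestClosedForms:
    def test_axial_strut_modulus(self):
        # member stiffness EA/L -> apparent modulus E_s * (A / loaded area)
        lat = single_strut()
        e = apparent_modulus(lat, [0, 0, 1], area=1.0)
        assert e == pytest.approx(2000.0, rel=1e-9)
        e_half = apparent_modulus(lat, [0, 0, 1], area=2.0)
        assert e_half == pytest.approx(1000.0, rel=1e-9)

    def test_cantilever_tip_deflection_euler(self):
        lat = single_strut(length=10.0, radius=0.2)
        clamp = {i: 0.0 for i in range(6)}
        P = 1.0
        u, _ = frame_solve(lat, clamp, loads={6 + 0: P}, shear=False)
        I = np.pi * 0.2**4 / 4
        assert u[6 + 0] == pytest.approx(P * 1000.0 / (3 * 2000.0 * I),
                                         rel=1e-9)

    def test_cantilever_tip_deflection_timoshenko(self):
        lat = single_strut(length=10.0, radius=0.5)
        clamp = {i: 0.0 for i in range(6)}
        P = 1.0
        u, _ = frame_solve(lat, clamp, loads={6 + 0: P}, shear=True)
        E, nu = 2000.0, 0.3
        G = E / (2 * (1 + nu))
        A = np.pi * 0.5**2
        I = np.pi * 0.5**4 / 4
        expected = P * 10.0**3 / (3 * E * I) + P * 10.0 / (_kappa(nu) * G * A)
        assert u[6 + 0] == pytest.approx(expected, rel=1e-9)

    def test_modulus_linear_in_material(self, test_material):
        lat = generate_cubic(np.array([2.0] * 3), 1.0, 0.08, MAT)
        stiff = Lattice(lat.nodes, lat.struts, lat.radii,
                        Material("2x", 4000.0, 0.3))
        e1 = apparent_modulus(lat, [0, 0, 1])
        e2 = apparent_modulus(stiff, [0, 0, 1])
        assert e2 == pytest.approx(2 * e1, rel=1e-9)


class TestSystemProperties:
    def test_stiffness_matrix_symmetric_with_six_rigid_modes(self):
        lat = generate_cubic(np.array([1.0] * 3), 1.0, 0.1, MAT)
        K = frame_stiffness(lat).toarray()
        np.testing.assert_allclose(K, K.T, atol=1e-8 * np.abs(K).max())
        w = np.linalg.eigvalsh(K)
        scale = w.max()
        assert np.all(w > -1e-9 * scale)          # PSD
        assert (np.abs(w) < 1e-9 * scale).sum() == 6  # rigid-body modes

    def test_rotation_and_scale_invariance(self):
        lat = generate_cubic(np.array([2.0] * 3), 1.0, 0.08, MAT)
        e0 = apparent_modulus(lat, [0, 0, 1])
        # rotate lattice and load together: modulus unchanged
        t = np.radians(30.0)
        rot = np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0],
                        [-np.sin(t), 0, np.cos(t)]])
        e_rot = apparent_modulus(lat.rotated(rot), rot @ [0, 0, 1])
        assert e_rot == pytest.approx(e0, rel=1e-6)
        # uniform geometric scaling (lengths and radii): modulus unchanged
        scaled = Lattice(lat.nodes * 2.0, lat.struts, lat.radii * 2.0, MAT)
        assert apparent_modulus(scaled, [0, 0, 1]) == pytest.approx(
            e0, rel=1e-9)

    def test_modulus_monotone_in_strut_radius(self):
        lat = generate_cubic(np.array([2.0] * 3), 1.0, 0.08, MAT)
        e0 = apparent_modulus(lat, [0, 0, 1])
        radii = lat.radii.copy()
        radii[0] *= 1.5
        e1 = apparent_modulus(lat.with_radii(radii), [0, 0, 1])
        assert e1 >= e0 - 1e-12

    def test_unbridged_faces_raise(self):
        # two stubs touch the platens but nothing connects them
        nodes = np.array([[0, 0, 0], [0, 0, 0.4], [1, 0, 0.6], [1, 0, 1.0]])
        struts = np.array([[0, 1], [2, 3]])
        lat = Lattice(nodes, struts, np.array([0.1, 0.1]), MAT)
        with pytest.raises(SingularityError):
            apparent_modulus(lat, [0, 0, 1], span=1.0, area=1.0)


@pytest.fixture(scope="module")
def cubic_sweep():
    block = generate_cubic(np.array([6.0] * 3), 1.0, 0.12, MAT)
    block = block.translated(-block.bbox().mean(axis=0))
    return direction_sweep(block, 30.0, test_diameter=3.0, test_height=3.0)


class TestDirectionSweep:

    def test_grid_covers_hemisphere_without_pole_duplicates(self,
                                                            cubic_sweep):
        pole = (cubic_sweep.theta_deg == 0.0)
        assert pole.sum() == 1
        assert cubic_sweep.theta_deg.max() == 90.0

    def test_cubic_lattice_stiffest_along_axis(self, cubic_sweep):
        k = int(np.argmax(cubic_sweep.moduli))
        theta = cubic_sweep.theta_deg[k]
        phi = cubic_sweep.phi_deg[k] % 90.0
        assert theta in (0.0, 90.0)
        if theta == 90.0:
            assert phi == pytest.approx(0.0, abs=1e-9)

    def test_anisotropy_and_average_bounds(self, cubic_sweep):
        ratio = anisotropy_coefficient(cubic_sweep)
        assert ratio >= 1.0
        avg = direction_average_modulus(cubic_sweep)
        assert cubic_sweep.moduli.min() <= avg <= cubic_sweep.moduli.max()

    def test_constant_sweep_average_and_ratio(self):
        phis, thetas = np.array([0.0, 10.0, 20.0]), np.array([0.0, 45.0,
                                                              90.0])
        sweep = DirectionSweep(phis, thetas, np.full(3, 123.0), 45.0)
        assert anisotropy_coefficient(sweep) == 1.0
        assert direction_average_modulus(sweep) == pytest.approx(123.0)

    def test_pole_duplicates_do_not_change_average(self):
        phis = np.array([0.0, 0.0, 90.0, 180.0, 270.0])
        thetas = np.array([0.0, 90.0, 90.0, 90.0, 90.0])
        moduli = np.array([5.0, 1.0, 2.0, 3.0, 4.0])
        base = direction_average_modulus(
            DirectionSweep(phis, thetas, moduli, 90.0))
        dup = direction_average_modulus(DirectionSweep(
            np.r_[phis, 120.0], np.r_[thetas, 0.0], np.r_[moduli, 5.0],
            90.0))
        assert dup == pytest.approx(base, rel=1e-9)


class TestHysteresis:
    def test_linear_curve_recovers_slope(self):
        strain = np.linspace(0, 0.01, 50)
        curve_stress = 1400.0 * strain
        from scaffold_regen.mechanics import StressStrainCurve
        curve = StressStrainCurve(strain, curve_stress,
                                  yield_estimate=curve_stress.max() / 0.7)
        assert modulus_from_hysteresis(curve) == pytest.approx(1400.0,
                                                               rel=1e-9)

    def test_loop_slope_not_toe_slope(self):
        curve = synthetic_hysteresis_curve(modulus=1400.0,
                                           yield_strength=10.0,
                                           toe_modulus=400.0)
        fit = modulus_from_hysteresis(curve)
        assert fit == pytest.approx(1400.0, rel=1e-6)
        assert abs(fit - 400.0) > 500.0

    def test_noise_does_not_bias_the_fit(self):
        fits = [modulus_from_hysteresis(synthetic_hysteresis_curve(
            1400.0, 10.0, noise_sd=0.05, seed=s)) for s in range(100)]
        fits = np.asarray(fits)
        se = fits.std(ddof=1) / np.sqrt(len(fits))
        assert abs(fits.mean() - 1400.0) <= 3 * se

    def test_window_not_covered_raises(self):
        from scaffold_regen.mechanics import StressStrainCurve
        strain = np.linspace(0, 0.001, 10)
        curve = StressStrainCurve(strain, 100.0 * strain,
                                  yield_estimate=1000.0)
        with pytest.raises(WindowError):
            modulus_from_hysteresis(curve)
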