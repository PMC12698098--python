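"""Stratified-media reflectance: recursion, transfer-matrix oracle, limits."""
import math

import numpy as np
import pytest

from thzskin import (
    FrequencyGrid,
    MaterialSpectrum,
    build_stack,
    interface_coefficient,
    phase_thickness,
    recursive_reflectance,
    transfer_matrix_reflectance,
)
from thzskin.dielectrics import SPEED_OF_LIGHT_UM_PS
from thzskin.errors import StackUsageError
from thzskin.ridge_stack import HALF_SPACE, Layer, RidgeStack


def flat(grid: FrequencyGrid, eps: complex) -> MaterialSpectrum:
    return MaterialSpectrum(grid, np.full(len(grid), eps, dtype=complex))


def simple_stack(grid, eps_list, thicknesses):
    layers = [Layer(HALF_SPACE, flat(grid, eps_list[0]))]
    for eps, d in zip(eps_list[1:-1], thicknesses):
        layers.append(Layer(d, flat(grid, eps)))
    layers.append(Layer(HALF_SPACE, flat(grid, eps_list[-1])))
    return RidgeStack(tuple(layers), L=max(len(eps_list) - 2, 1), d_f_um=1.0, V_A1=0.0)


def random_lossy_stack(grid, rng, max_layers=30):
    m = int(rng.integers(1, max_layers + 1))
    eps = [1.0 + 0j]
    for _ in range(m):
        eps.append(rng.uniform(1.2, 9.0) - 1j * rng.uniform(0.0, 2.0))
    eps.append(rng.uniform(2.0, 9.0) - 1j * rng.uniform(0.0, 1.0))
    d = rng.uniform(0.5, 60.0, size=m)
    return simple_stack(grid, eps, d)


@pytest.fixture(scope="module")
def small_grid():
    return FrequencyGrid(np.linspace(0.1, 2.0, 32))


class TestInterfaceCoefficient:
    def test_no_interface_gives_zero(self):
        assert interface_coefficient(2.5 - 0.3j, 2.5 - 0.3j) == pytest.approx(0.0)

    def test_air_quartz_closed_form(self):
        r = interface_coefficient(1.0, 1.98**2)
        assert r == pytest.approx((1 - 1.98) / (1 + 1.98), abs=1e-5)
        assert r == pytest.approx(-0.32886, abs=1e-5)

    def test_s_and_p_coincide_at_normal_incidence(self):
        rs = interface_coefficient(2.0, 5.0 - 1.0j, 0.0, "s")
        rp = interface_coefficient(2.0, 5.0 - 1.0j, 0.0, "p")
        assert rs == pytest.approx(rp, rel=1e-12)


class TestPhaseThickness:
    def test_quarter_wave_is_half_pi(self, small_grid):
        f = 1.0
        lam = SPEED_OF_LIGHT_UM_PS / f
        n = 2.0
        layer = Layer(lam / (4 * n), flat(small_grid, n * n))
        delta = phase_thickness(layer, f)
        assert np.allclose(delta, np.pi / 2, rtol=1e-12)

    def test_null_layer_has_zero_phase(self, small_grid):
        layer = Layer(0.0, flat(small_grid, 4.0))
        assert np.allclose(phase_thickness(layer, 1.3), 0.0)

    def test_direct_evaluation(self, small_grid):
        layer = Layer(75.0, flat(small_grid, 4.0))
        delta = phase_thickness(layer, 1.0)
        assert np.allclose(delta, 2 * np.pi * 2.0 * 75.0 / 299.792458)
        assert np.allclose(delta, 3.1437, atol=5e-5)

    def test_half_space_rejected(self, small_grid):
        with pytest.raises(StackUsageError):
            phase_thickness(Layer(HALF_SPACE, flat(small_grid, 4.0)), 1.0)


class TestRecursiveReflectance:
    def test_two_half_spaces_reduce_to_interface(self, small_grid):
        stack = simple_stack(small_grid, [1.0, 4.0 - 0.5j], [])
        r = recursive_reflectance(stack).r
        expected = interface_coefficient(1.0, 4.0 - 0.5j)
        assert np.allclose(r, expected, atol=1e-14)

    def test_null_layer_is_a_no_op(self, small_grid, rng):
        for _ in range(50):
            stack = random_lossy_stack(small_grid, rng, max_layers=6)
            eps = [l.permittivity.eps[0] for l in stack.layers]
            d = [l.thickness_um for l in stack.layers]
            pos = int(rng.integers(1, len(eps)))
            eps2 = eps[:pos] + [rng.uniform(1.0, 9.0) - 1j * rng.uniform(0, 2)] + eps[pos:]
            d2 = [HALF_SPACE] + [x for x in d[1:-1]] + [HALF_SPACE]
            d2 = d2[:pos] + [0.0] + d2[pos:]
            with_null = simple_stack(small_grid, eps2, d2[1:-1])
            r0 = recursive_reflectance(stack).r
            r1 = recursive_reflectance(with_null).r
            np.testing.assert_allclose(r1, r0, atol=1e-12)

    def test_degenerate_single_medium_rejected(self, small_grid):
        from thzskin.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            RidgeStack((Layer(HALF_SPACE, flat(small_grid, 1.0)),), L=1, d_f_um=1.0, V_A1=0.0)

    def test_identical_half_spaces_reflect_nothing(self, small_grid):
        lone = RidgeStack(
            (Layer(HALF_SPACE, flat(small_grid, 1.0)), Layer(HALF_SPACE, flat(small_grid, 1.0))),
            L=1, d_f_um=1.0, V_A1=0.0,
        )
        assert np.allclose(recursive_reflectance(lone).r, 0.0)

    def test_passivity_bound_on_random_stacks(self, small_grid, rng):
        for _ in range(25):
            stack = random_lossy_stack(small_grid, rng)
            assert np.all(np.abs(recursive_reflectance(stack).r) <= 1 + 1e-9)

    def test_continuity_in_va1(self, stack_config, small_grid):
        # r is smooth in the deformation parameter: central differences shrink
        h = 1e-4
        r = lambda v: recursive_reflectance(build_stack(stack_config, small_grid, V_A1=v)).r
        d1 = (r(0.5 + h) - r(0.5 - h)) / (2 * h)
        d1_coarse = (r(0.5 + 10 * h) - r(0.5 - 10 * h)) / (20 * h)
        assert np.max(np.abs(d1 - d1_coarse)) < 1e-2 * (1 + np.max(np.abs(d1)))

    def test_flattened_limit_is_continuous(self, stack_config, small_grid):
        r0 = recursive_reflectance(build_stack(stack_config, small_grid, V_A1=0.0)).r
        r_eps = recursive_reflectance(build_stack(stack_config, small_grid, V_A1=1e-6)).r
        np.testing.assert_allclose(r_eps, r0, atol=1e-5)


class TestTransferMatrixOracle:
    def test_agrees_with_recursion_on_random_stacks(self, small_grid, rng):
        worst = 0.0
        for _ in range(100):
            stack = random_lossy_stack(small_grid, rng)
            r1 = recursive_reflectance(stack).r
            r2 = transfer_matrix_reflectance(stack).r
            worst = max(worst, float(np.max(np.abs(r1 - r2))))
        assert worst <= 1e-10

    def test_agreement_at_oblique_incidence_both_polarizations(self, small_grid, rng):
        for pol in ("s", "p"):
            for _ in range(10):
                stack = random_lossy_stack(small_grid, rng, max_layers=8)
                r1 = recursive_reflectance(stack, angle=0.5, polarization=pol).r
                r2 = transfer_matrix_reflectance(stack, angle=0.5, polarization=pol).r
                np.testing.assert_allclose(r1, r2, atol=1e-10)

    def test_quarter_wave_antireflection_coating(self):
        n1, n3 = 1.0, 4.0
        n2 = math.sqrt(n1 * n3)
        f0 = 1.0
        d = SPEED_OF_LIGHT_UM_PS / f0 / (4 * n2)
        grid = FrequencyGrid(np.array([f0, 2 * f0]))
        stack = simple_stack(grid, [n1**2, n2**2, n3**2], [d])
        r = transfer_matrix_reflectance(stack).r
        assert abs(r[0]) < 1e-12  # design frequency
        assert abs(r[1]) > 0.1  # away from design

    def test_lossless_stack_conserves_energy(self, small_grid):
        # for a lossless stack |r| <= 1 with equality only at total reflection
        stack = simple_stack(small_grid, [1.0, 2.25, 4.0, 2.89], [40.0, 25.0])
        r = transfer_matrix_reflectance(stack).r
        assert np.all(np.abs(r) <= 1 + 1e-12)
        assert np.all(np.abs(r) < 1 - 1e-6)
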