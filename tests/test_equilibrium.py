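"""Competition-equilibrium solver: exact roots, conservation, buffering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import bisect

from rcsbuffer.equilibrium import (
    BindingSystem,
    buffer_curve,
    kd_ratio,
    linearized_complexes,
    solve_competition,
)


def mass_balance(r, sys_):
    return r + sys_.a_total * r / (sys_.kd_a + r) + sys_.i_total * r / (sys_.kd_i + r) - sys_.r_total


def random_systems(n, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        r, a, i = 10.0 ** rng.uniform(-3, 4, 3)
        ka, ki = 10.0 ** rng.uniform(-4, 4, 2)
        yield BindingSystem(r, a, i, ka, ki)


class TestSolveCompetition:
    def test_no_ligand_gives_empty_state(self):
        state = solve_competition(BindingSystem(0.0, 1000.0, 1.0, 125.0, 0.0016))
        assert state.free_r == 0.0
        assert state.complex_ar == 0.0 and state.complex_ir == 0.0
        assert state.free_a == 1000.0 and state.free_i == 1.0

    def test_physiological_system_root(self, physiological_system):
        # frozen digits confirmed by independent bisection on the mass balance
        state = solve_competition(physiological_system)
        assert state.free_r == pytest.approx(1.5730460281, rel=1e-8)
        assert state.complex_ar == pytest.approx(12.42797007, rel=1e-8)
        assert state.complex_ir == pytest.approx(0.9989838986, rel=1e-8)

    def test_single_receptor_reduces_to_quadratic(self):
        # A_total = 0: closed-form single-site solution
        state = solve_competition(BindingSystem(2.0, 0.0, 1.0, 1.0, 1.0))
        i_tot, r_tot, kd = 1.0, 2.0, 1.0
        s = i_tot + r_tot + kd
        expected = (s - np.sqrt(s * s - 4 * i_tot * r_tot)) / 2
        assert state.complex_ir == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.5857864376, rel=1e-8)

    @pytest.mark.parametrize("bad", [
        dict(r_total=-1.0, a_total=1.0, i_total=1.0, kd_a=1.0, kd_i=1.0),
        dict(r_total=1.0, a_total=np.nan, i_total=1.0, kd_a=1.0, kd_i=1.0),
        dict(r_total=1.0, a_total=1.0, i_total=1.0, kd_a=0.0, kd_i=1.0),
        dict(r_total=1.0, a_total=1.0, i_total=1.0, kd_a=1.0, kd_i=-2.0),
    ])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            BindingSystem(**bad)

    def test_agrees_with_bisection_oracle(self):
        for sys_ in random_systems(200, seed=11):
            state = solve_competition(sys_)
            oracle = bisect(mass_balance, 0.0, sys_.r_total, args=(sys_,), xtol=1e-15)
            assert state.free_r == pytest.approx(oracle, rel=1e-9, abs=1e-15)

    def test_conservation_and_mass_action(self):
        for sys_ in random_systems(200, seed=23):
            s = solve_competition(sys_)
            assert s.free_a + s.complex_ar == pytest.approx(sys_.a_total, rel=1e-9)
            assert s.free_i + s.complex_ir == pytest.approx(sys_.i_total, rel=1e-9)
            assert s.free_r + s.complex_ar + s.complex_ir == pytest.approx(sys_.r_total, rel=1e-9)
            assert s.complex_ar * sys_.kd_a == pytest.approx(s.free_a * s.free_r, rel=1e-9, abs=1e-300)
            assert s.complex_ir * sys_.kd_i == pytest.approx(s.free_i * s.free_r, rel=1e-9, abs=1e-300)
            assert min(s.free_r, s.free_a, s.free_i, s.complex_ar, s.complex_ir) >= 0
            assert s.complex_ir <= min(sys_.i_total, sys_.r_total) * (1 + 1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        r=st.floats(1e-3, 1e4), a=st.floats(0, 1e4), i=st.floats(0, 1e4),
        ka=st.floats(1e-4, 1e4), ki=st.floats(1e-4, 1e4),
    )
    def test_root_property(self, r, a, i, ka, ki):
        sys_ = BindingSystem(r, a, i, ka, ki)
        state = solve_competition(sys_)
        assert abs(mass_balance(state.free_r, sys_)) <= 1e-8 * r


class TestLinearized:
    def test_half_saturation_and_origin(self, physiological_system):
        sys_ = physiological_system
        _, ir = linearized_complexes(sys_.kd_i, sys_)
        assert ir == pytest.approx(sys_.i_total / 2)
        assert linearized_complexes(0.0, sys_) == (0.0, 0.0)

    def test_linear_term_vs_exact(self, physiological_system):
        # at free R = 1.573 µM the constant-receptor approximation overshoots by ~1.2%
        ar, _ = linearized_complexes(1.573, physiological_system)
        assert ar == pytest.approx(12.584, rel=1e-9)
        exact_ar = solve_competition(physiological_system).complex_ar
        rel_dev = (ar - exact_ar) / exact_ar
        assert rel_dev == pytest.approx(1.573 / (125.0 + 1.573), rel=0.05)

    def test_limit_agreement(self):
        # dilute-ligand regime: linearized A-complex matches exact within 1.5%
        for sys_ in [
            BindingSystem(0.5, 100.0, 0.1, 100.0, 0.01),
            BindingSystem(1.0, 500.0, 1.0, 200.0, 0.001),
            BindingSystem(0.01, 10.0, 0.001, 10.0, 0.1),
        ]:
            assert sys_.r_total <= 0.01 * sys_.kd_a and sys_.a_total >= 100 * sys_.r_total
            state = solve_competition(sys_)
            lin_ar, _ = linearized_complexes(state.free_r, sys_)
            assert lin_ar == pytest.approx(state.complex_ar, rel=0.015)

    def test_negative_free_r_rejected(self, physiological_system):
        with pytest.raises(ValueError):
            linearized_complexes(-0.1, physiological_system)


class TestKdRatio:
    @pytest.mark.parametrize("kd_a, kd_i, expected", [
        (125.0, 0.0016, 78125.0),
        (1.0, 1.0, 1.0),
        (0.4, 0.0016, 250.0),
    ])
    def test_fold_difference(self, kd_a, kd_i, expected):
        assert kd_ratio(kd_a, kd_i) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            kd_ratio(0.0, 1.0)
        with pytest.raises(ValueError):
            kd_ratio(1.0, -1.0)


class TestBufferCurve:
    def test_linearized_hyperbola_points(self, physiological_system):
        sys_ = physiological_system
        curve = buffer_curve(sys_, [0.0, sys_.kd_i, 10 * sys_.kd_i], mode="linearized")
        np.testing.assert_allclose(
            curve.complex_ir, [0.0, sys_.i_total / 2, sys_.i_total * 10 / 11], rtol=1e-12
        )
        # linear A-complex: exactly proportional to the free-ligand grid
        np.testing.assert_allclose(
            curve.complex_ar, np.array([0.0, sys_.kd_i, 10 * sys_.kd_i]) * sys_.a_total / sys_.kd_a
        )

    def test_exact_curve_monotone_and_bounded(self, physiological_system):
        grid = np.linspace(0, 15, 40)
        curve = buffer_curve(physiological_system, grid, mode="exact", axis="total")
        assert np.all(np.diff(curve.complex_ir) >= -1e-12)
        assert np.all(np.diff(curve.complex_ar) >= -1e-12)
        assert np.all(curve.complex_ir <= physiological_system.i_total + 1e-12)

    def test_buffering_doubling_a_total_suppresses_ir(self, physiological_system):
        sys_ = physiological_system
        doubled = BindingSystem(sys_.r_total, 2 * sys_.a_total, sys_.i_total, sys_.kd_a, sys_.kd_i)
        grid = np.linspace(0.5, 15, 20)
        base = buffer_curve(sys_, grid, mode="exact", axis="total")
        more = buffer_curve(doubled, grid, mode="exact", axis="total")
        assert np.all(more.complex_ir < base.complex_ir)

    def test_monotone_in_r_total(self, physiological_system):
        sys_ = physiological_system
        ir = [
            solve_competition(BindingSystem(r, sys_.a_total, sys_.i_total, sys_.kd_a, sys_.kd_i)).complex_ir
            for r in np.linspace(0, 30, 15)
        ]
        assert np.all(np.diff(ir) >= -1e-12)

    def test_grid_validation(self, physiological_system):
        with pytest.raises(ValueError):
            buffer_curve(physiological_system, [])
        with pytest.raises(ValueError):
            buffer_curve(physiological_system, [1.0, 0.5])
        with pytest.raises(ValueError):
            buffer_curve(physiological_system, [0.0, 1.0], mode="approximate")
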