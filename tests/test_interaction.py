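"""Interphase-force unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemoflow.fields import TensorField2D
from hemoflow.interaction import (
    InteractionParams,
    drag_force,
    hindrance,
    saffman_lift,
    spin_lift,
    total_interaction,
)


def _simple_shear(n, gamma):
    """D and W for du/dy = gamma."""
    D = TensorField2D(xx=np.zeros(n), xy=np.full(n, gamma / 2), yy=np.zeros(n))
    W = TensorField2D(xx=np.zeros(n), xy=np.full(n, gamma / 2),
                      yy=np.zeros(n), yx=np.full(n, -gamma / 2))
    return D, W


class TestHindrance:
    @pytest.mark.parametrize("phi,expected", [(0.0, 0.0), (0.2, 0.462), (0.4, 1.448)])
    def test_values(self, phi, expected):
        assert hindrance(phi) == pytest.approx(expected, rel=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            hindrance(1.5)


class TestDrag:
    def test_zero_slip(self):
        n = 4
        v = np.random.default_rng(0).normal(0, 1, (n, 2))
        f = drag_force(np.full(n, 0.3), v, v.copy())
        np.testing.assert_allclose(f, 0.0)

    def test_worked_magnitude(self):
        # phi=0.2, slip 0.01 m/s: (9 mu/(2 a^2)) f(phi) |slip| ~ 3.119e5 N/m^3
        n = 1
        vp = np.zeros((n, 2))
        vr = np.array([[0.01, 0.0]])
        f = drag_force(np.full(n, 0.2), vp, vr)
        assert np.linalg.norm(f[0]) == pytest.approx(
            9 * 0.96e-3 / (2 * (8e-6) ** 2) * 0.462 * 0.01, rel=1e-12
        )

    def test_linearity_in_slip(self):
        n = 1
        vp = np.zeros((n, 2))
        vr = np.array([[0.01, 0.003]])
        f1 = drag_force(np.full(n, 0.2), vp, vr)
        f2 = drag_force(np.full(n, 0.2), vp, 2 * vr)
        np.testing.assert_allclose(f2, 2 * f1)


class TestSaffman:
    def test_zero_on_zero_slip_or_zero_strain(self):
        n = 2
        D, _ = _simple_shear(n, 100.0)
        v = np.random.default_rng(1).normal(0, 1, (n, 2))
        np.testing.assert_allclose(saffman_lift(np.full(n, 0.2), D, v, v.copy()), 0.0)
        D0 = TensorField2D.zeros(n)
        vr = v + np.array([0.01, 0.0])
        np.testing.assert_allclose(saffman_lift(np.full(n, 0.2), D0, v, vr), 0.0)

    def test_regression_simple_shear(self):
        # phi=0.2, gamma=100/s, slip (0.01, 0): frozen scalar hand-evaluation
        # of the prefactor (3*6.46/(4 pi a)) sqrt(rho mu) phi gdot^(-1/2) D.slip
        n = 1
        D, _ = _simple_shear(n, 100.0)
        vp = np.zeros((n, 2))
        vr = np.array([[0.01, 0.0]])
        f = saffman_lift(np.full(n, 0.2), D, vp, vr)
        pref = 3 * 6.46 * np.sqrt(1027 * 0.96e-3) / (4 * np.pi * 8e-6)
        expect_y = pref * 0.2 * 100 ** (-0.5) * 50.0 * 0.01
        assert f[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert f[0, 1] == pytest.approx(expect_y, rel=1e-12)
        assert f[0, 1] == pytest.approx(1914.15, rel=1e-4)  # frozen value

    def test_shear_floor_continuity(self):
        # crossing the regularization threshold changes nothing abruptly
        n = 1
        params = InteractionParams(shear_floor=1.0)
        vp = np.zeros((n, 2))
        vr = np.array([[0.01, 0.0]])
        eps = 1e-9
        lo = saffman_lift(np.full(n, 0.2), _simple_shear(n, 1.0 - eps)[0], vp, vr, params=params)
        hi = saffman_lift(np.full(n, 0.2), _simple_shear(n, 1.0 + eps)[0], vp, vr, params=params)
        np.testing.assert_allclose(lo, hi, rtol=1e-6)


class TestSpinLift:
    def test_worked_magnitude_and_direction(self):
        # spin difference 50/s, slip (0.01, 0): 0.75*1027*0.2*50*0.01 = 77.0
        n = 1
        _, Wp = _simple_shear(n, 0.0)
        w = 50.0
        Wr = TensorField2D(xx=np.zeros(n), xy=np.full(n, w), yy=np.zeros(n),
                           yx=np.full(n, -w))
        vp = np.zeros((n, 2))
        vr = np.array([[0.01, 0.0]])
        f = spin_lift(np.full(n, 0.2), Wp, Wr, vp, vr)
        assert abs(f[0, 0]) < 1e-12  # transverse to slip
        assert abs(f[0, 1]) == pytest.approx(77.025, rel=1e-10)

    def test_zero_cases(self):
        n = 2
        _, W = _simple_shear(n, 40.0)
        v = np.random.default_rng(2).normal(0, 1, (n, 2))
        np.testing.assert_allclose(spin_lift(np.full(n, 0.2), W, W, v, v + 0.01), 0.0)
        W2 = TensorField2D(xx=np.zeros(n), xy=np.full(n, 99.0), yy=np.zeros(n),
                           yx=np.full(n, -99.0))
        np.testing.assert_allclose(spin_lift(np.full(n, 0.2), W, W2, v, v.copy()), 0.0)

    def test_orthogonal_to_slip(self):
        n = 8
        rng = np.random.default_rng(3)
        w = rng.normal(0, 30, n)
        Wp = TensorField2D(xx=np.zeros(n), xy=np.zeros(n), yy=np.zeros(n), yx=np.zeros(n))
        Wr = TensorField2D(xx=np.zeros(n), xy=w, yy=np.zeros(n), yx=-w)
        vp = rng.normal(0, 0.1, (n, 2))
        vr = rng.normal(0, 0.1, (n, 2))
        f = spin_lift(rng.uniform(0.05, 0.5, n), Wp, Wr, vp, vr)
        dots = np.einsum("ij,ij->i", f, vr - vp)
        np.testing.assert_allclose(dots, 0.0, atol=1e-9)

    def test_rejects_non_antisymmetric(self):
        n = 1
        bad = TensorField2D(xx=np.ones(n), xy=np.ones(n), yy=np.zeros(n), yx=np.ones(n))
        good = TensorField2D(xx=np.zeros(n), xy=np.ones(n), yy=np.zeros(n), yx=-np.ones(n))
        with pytest.raises(ValueError):
            spin_lift(np.full(n, 0.2), bad, good, np.zeros((n, 2)), np.ones((n, 2)))


class TestTotalInteraction:
    def _fields(self, n=16, seed=4):
        rng = np.random.default_rng(seed)
        phi = rng.uniform(0.05, 0.6, n)
        vp = rng.normal(0, 0.2, (n, 2))
        vr = rng.normal(0, 0.2, (n, 2))
        D = TensorField2D(xx=rng.normal(0, 200, n), xy=rng.normal(0, 200, n),
                          yy=rng.normal(0, 200, n))
        w1, w2 = rng.normal(0, 100, n), rng.normal(0, 100, n)
        Wp = TensorField2D(xx=np.zeros(n), xy=w1, yy=np.zeros(n), yx=-w1)
        Wr = TensorField2D(xx=np.zeros(n), xy=w2, yy=np.zeros(n), yx=-w2)
        return phi, vp, vr, D, Wp, Wr

    def test_all_disabled_zero(self):
        phi, vp, vr, D, Wp, Wr = self._fields()
        params = InteractionParams(enable_drag=False, enable_saffman=False,
                                   enable_spin=False)
        np.testing.assert_allclose(
            total_interaction(phi, vp, vr, D, Wp, Wr, params=params), 0.0)

    def test_only_drag_equals_drag(self):
        phi, vp, vr, D, Wp, Wr = self._fields()
        params = InteractionParams(enable_saffman=False, enable_spin=False)
        np.testing.assert_allclose(
            total_interaction(phi, vp, vr, D, Wp, Wr, params=params),
            drag_force(phi, vp, vr))

    def test_galilean_invariance(self):
        phi, vp, vr, D, Wp, Wr = self._fields()
        f0 = total_interaction(phi, vp, vr, D, Wp, Wr)
        shift = np.array([0.37, -1.2])
        f1 = total_interaction(phi, vp + shift, vr + shift, D, Wp, Wr)
        np.testing.assert_allclose(f0, f1, rtol=1e-12, atol=1e-12)

    def test_dilute_drag_limit(self):
        # drag / phi -> (9 mu / 2 a^2) * slip * (1 + O(phi)) as phi -> 0
        slip = np.array([[0.01, 0.0]])
        vp = np.zeros((1, 2))
        k0 = 9 * 0.96e-3 / (2 * (8e-6) ** 2)
        for phi in (1e-3, 1e-5):
            f = drag_force(np.array([phi]), vp, slip)
            per_phi = np.linalg.norm(f[0]) / phi
            assert per_phi == pytest.approx(k0 * 0.01, rel=10 * phi)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 1000))
    def test_pairwise_closure(self, seed):
        # the same fI is added to the plasma and subtracted from the RBC
        # momentum balance, so the exchange closes cell-wise by construction
        phi, vp, vr, D, Wp, Wr = self._fields(seed=seed)
        fI = total_interaction(phi, vp, vr, D, Wp, Wr)
        np.testing.assert_allclose(fI + (-fI), 0.0)
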