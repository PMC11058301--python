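"""Finite-volume solver tests: gradients, limits, conservation, invariance."""

import numpy as np
import pytest

import hemoflow as hf
from hemoflow.mesh import StructuredGrid
from hemoflow.solver import (
    FlowState,
    TwoFluidSolver,
    compute_velocity_gradients,
    phase_mass_balance,
)

SINGLE_PHASE = hf.InteractionParams(enable_drag=False, enable_saffman=False,
                                    enable_spin=False)


def _state_with(grid, u_p, v_p, u_r=None, v_r=None, phi=0.2):
    n = grid.ncell
    vp = np.stack([u_p, v_p], axis=1)
    vr = vp.copy() if u_r is None else np.stack([u_r, v_r], axis=1)
    return FlowState(
        phi=np.full(n, phi), p=np.zeros(n), vp=vp, vr=vr,
        residual_history={}, converged=True, iterations=0, clipped_rbc_volume=0.0,
    )


class TestVelocityGradients:
    def test_uniform_field_zero(self):
        g = hf.build_uniform_grid(1e-3, 50e-6, 12, 6)
        st = _state_with(g, np.full(g.ncell, 0.3), np.zeros(g.ncell))
        Dp, Dr, Wp, Wr = compute_velocity_gradients(st, g)
        for t in (Dp.xx, Dp.xy, Dp.yy, Wp.xy):
            np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_linear_shear_exact(self):
        gamma = 40.0
        g = hf.build_uniform_grid(1e-3, 50e-6, 12, 6)
        st = _state_with(g, gamma * g.yc, np.zeros(g.ncell))
        Dp, _, Wp, _ = compute_velocity_gradients(st, g)
        ids = g.blocks[0].cells[1:-1, 1:-1].ravel()
        np.testing.assert_allclose(Dp.xy[ids], gamma / 2, rtol=1e-12)
        np.testing.assert_allclose(Wp.xy[ids], gamma / 2, rtol=1e-12)
        np.testing.assert_allclose(Wp.get_yx()[ids], -gamma / 2, rtol=1e-12)

    def test_rigid_rotation(self):
        omega = 10.0
        g = hf.build_uniform_grid(1e-3, 50e-6, 12, 6)
        st = _state_with(g, -omega * g.yc, omega * g.xc)
        Dp, _, Wp, _ = compute_velocity_gradients(st, g)
        ids = g.blocks[0].cells[1:-1, 1:-1].ravel()
        np.testing.assert_allclose(Dp.xy[ids], 0.0, atol=1e-9 * omega)
        np.testing.assert_allclose(Wp.xy[ids], -omega, rtol=1e-9)

    def test_axisymmetric_hoop(self):
        g = hf.build_uniform_grid(1e-3, 50e-6, 12, 6, mode="axisymmetric")
        v = 2.0 * g.yc  # radial velocity ~ r -> D_tt = v/r = 2
        st = _state_with(g, np.zeros(g.ncell), v)
        Dp, _, _, _ = compute_velocity_gradients(st, g)
        np.testing.assert_allclose(Dp.tt, 2.0, rtol=1e-12)


class TestSinglePhaseLimits:
    def test_planar_poiseuille(self, planar_poiseuille_120x16):
        state, grid, bc = planar_poiseuille_120x16
        assert state.converged
        exit_ids = grid.blocks[0].cells[-1, :]
        ratio = state.vp[exit_ids[0], 0] / bc.inlet_velocity_Vt
        assert ratio == pytest.approx(1.5, rel=0.02)

    def test_reduction_to_single_phase_as_phi_vanishes(self):
        # with interactions off and phi pinned, the plasma momentum carries a
        # uniform (1-phi) factor: the field must become independent of Ht
        g = hf.build_uniform_grid(0.5e-3, 50e-6, 40, 8)
        sols = []
        for ht in (1e-9, 1e-12):
            bc = hf.BoundaryConditions(inlet_velocity_Vt=0.2, inlet_hematocrit_Ht=ht)
            cfg = hf.SolverConfig(max_outer=2000, tol=1e-10, freeze_phi=True,
                                  phi_min=ht)
            sols.append(hf.steady_solve(g, bc, params=SINGLE_PHASE, config=cfg))
        diff = np.abs(sols[0].vp - sols[1].vp).max()
        assert diff < 1e-8

    def test_drag_tightens_slip_with_smaller_rbc_size(self):
        # (9 mu / 2 a^2): halving a quadruples the drag and shrinks the slip
        g = hf.build_uniform_grid(0.5e-3, 50e-6, 40, 8)
        bc = hf.BoundaryConditions(inlet_velocity_Vt=0.2, inlet_hematocrit_Ht=0.2)
        params = hf.InteractionParams(enable_saffman=False, enable_spin=False)
        cfg = hf.SolverConfig(max_outer=1500, tol=1e-6)
        slips = []
        for a in (16e-6, 8e-6, 4e-6):
            props = hf.FluidProperties(rbc_size_a=a)
            st = hf.steady_solve(g, bc, props=props, params=params, config=cfg)
            assert st.converged
            slips.append(np.abs(st.vr - st.vp).max())
        assert slips[0] > slips[1] > slips[2]


class TestConservationAndInvariance:
    def test_phase_mass_balance(self, stenosis_base_run):
        state, grid, bc = stenosis_base_run
        assert state.converged
        bal = phase_mass_balance(state, grid, bc)
        assert bal["plasma"]["rel_imbalance"] < 1e-6
        assert bal["rbc"]["rel_imbalance"] < 1e-6

    def test_phi_approaches_uniform_as_phases_lock(self):
        # even without lifts the phases develop different entrance profiles
        # (the RBC phase is far more viscous), so phi redistributes; tighter
        # drag coupling (smaller a) locks the phases and flattens phi
        g = hf.build_uniform_grid(0.5e-3, 50e-6, 40, 8)
        bc = hf.BoundaryConditions(inlet_velocity_Vt=0.2, inlet_hematocrit_Ht=0.2)
        cfg = hf.SolverConfig(max_outer=1500, tol=1e-7)
        dev = []
        for a in (8e-6, 2e-6):
            params = hf.InteractionParams(enable_saffman=False, enable_spin=False)
            props = hf.FluidProperties(rbc_size_a=a)
            st = hf.steady_solve(g, bc, props=props, params=params, config=cfg)
            assert st.converged
            dev.append(np.abs(st.phi - 0.2).max())
        assert dev[1] < dev[0] / 4

    def test_determinism_bit_identical(self):
        g = hf.build_uniform_grid(0.5e-3, 50e-6, 30, 6)
        bc = hf.BoundaryConditions(inlet_velocity_Vt=0.2, inlet_hematocrit_Ht=0.2)
        cfg = hf.SolverConfig(max_outer=60, tol=1e-12)
        s1 = hf.steady_solve(g, bc, config=cfg)
        s2 = hf.steady_solve(g, bc, config=cfg)
        for k in s1.residual_history:
            np.testing.assert_array_equal(
                s1.residual_history[k], s2.residual_history[k])
        np.testing.assert_array_equal(s1.vp, s2.vp)

    def test_mirrored_geometry_mirrors_fields(self):
        # a channel built upside-down (wall below, symmetry above) must give
        # the mirrored solution
        L, h, nx, ny = 0.5e-3, 50e-6, 30, 8
        g1 = hf.build_uniform_grid(L, h, nx, ny)
        xn = np.linspace(0.0, L, nx + 1)
        yn = np.linspace(0.0, h, ny + 1)
        X = np.repeat(xn[:, None], ny + 1, axis=1)
        Y = np.repeat(yn[None, :], nx + 1, axis=0)
        Ym = -Y[:, ::-1]  # y -> -y, reordered to keep orientation
        tags = {"west": "inlet", "east": "outlet", "south": "wall",
                "north": "symmetry"}
        g2 = StructuredGrid([(X, Ym)], [tags], [], "planar")
        bc = hf.BoundaryConditions(inlet_velocity_Vt=0.2, inlet_hematocrit_Ht=0.2)
        cfg = hf.SolverConfig(max_outer=800, tol=1e-9)
        s1 = hf.steady_solve(g1, bc, config=cfg)
        s2 = hf.steady_solve(g2, bc, config=cfg)
        c1 = g1.blocks[0].cells
        c2 = g2.blocks[0].cells[:, ::-1]  # j reversed
        np.testing.assert_allclose(s1.vp[c1, 0], s2.vp[c2, 0], atol=1e-10)
        np.testing.assert_allclose(s1.vp[c1, 1], -s2.vp[c2, 1], atol=1e-10)
        np.testing.assert_allclose(s1.phi[c1], s2.phi[c2], atol=1e-10)

    def test_slip_bounded(self, stenosis_small_run):
        state, grid, _ = stenosis_small_run
        assert np.abs(state.vr - state.vp).max() <= np.abs(state.vp).max()


class TestPhiTransport:
    def test_step_advection_monotone(self):
        # first-order upwind must not create new extrema in a 1D step
        g = hf.build_uniform_grid(1e-3, 50e-6, 50, 4)
        bc = hf.BoundaryConditions(inlet_velocity_Vt=0.2, inlet_hematocrit_Ht=0.3)
        s = TwoFluidSolver(g, bc, config=hf.SolverConfig(relax_phi=1.0,
                                                         phi_pseudo_cfl=0.5))
        # impose a uniform rightward RBC face flux and a phi step
        s.f_G["r"] = np.where(np.abs(g.f_Sw[:, 0]) > 0,
                              0.2 * g.f_Sw[:, 0], 0.0)
        s.b_G["r"] = np.where(g.b_tag == 1, 0.2 * np.abs(g.b_Sw[:, 0]),
                              np.where(g.b_tag == 0, -0.2 * np.abs(g.b_Sw[:, 0]), 0.0))
        cells = g.blocks[0].cells
        phi0 = np.where(g.xc < 0.4e-3, 0.3, 0.05)
        s.phi = phi0.copy()
        for _ in range(10):
            s.transport_phi({})
            assert s.phi.max() <= 0.3 + 1e-12
            assert s.phi.min() >= 0.05 - 1e-12
            prof = s.phi[cells[:, 1]]
            assert np.all(np.diff(prof) <= 1e-12)  # stays monotone

    def test_nonconvergence_flagged(self):
        g = hf.build_uniform_grid(0.5e-3, 50e-6, 20, 5)
        bc = hf.BoundaryConditions(inlet_velocity_Vt=0.2, inlet_hematocrit_Ht=0.2)
        st = hf.steady_solve(g, bc, config=hf.SolverConfig(max_outer=3, tol=1e-14))
        assert not st.converged
        assert st.iterations == 3
        assert len(st.residual_history["u_p"]) == 3
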