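"""Post-processing tests: wall shear stress, sections, layers, outputs."""

import numpy as np
import pandas as pd
import pytest
import yaml

import hemoflow as hf
from hemoflow.postprocess import (
    LayerThresholds,
    layer_metrics,
    recirculation_extent,
    section_profile,
    wall_shear_stress,
    write_outputs,
)
from hemoflow.solver import FlowState
from hemoflow.vtkio import read_vtk_structured, write_vtk_structured


def _state(grid, u, v=None, phi=0.2, p=None):
    n = grid.ncell
    vp = np.stack([u, np.zeros(n) if v is None else v], axis=1)
    return FlowState(
        phi=np.full(n, phi) if np.isscalar(phi) else phi,
        p=np.zeros(n) if p is None else p,
        vp=vp, vr=vp.copy(),
        residual_history={"u_p": np.array([0.0])},
        converged=True, iterations=1, clipped_rbc_volume=0.0,
    )


class TestWallShearStress:
    def test_analytic_linear_shear(self):
        # u = U0 (1 - y/h): one-sided traction equals mu (1-phi) U0/h exactly
        g = hf.build_uniform_grid(1e-3, 50e-6, 20, 8)
        U0, h, phi = 0.3, 50e-6, 0.2
        st = _state(g, U0 * (1 - g.yc / h), phi=phi)
        wall = wall_shear_stress(st, g)
        mu = hf.FluidProperties().plasma_viscosity
        np.testing.assert_allclose(wall.tau_wss, mu * (1 - phi) * U0 / h, rtol=1e-8)

    def test_quiescent_zero(self):
        g = hf.build_uniform_grid(1e-3, 50e-6, 10, 5)
        st = _state(g, np.zeros(g.ncell))
        assert np.all(wall_shear_stress(st, g).tau_wss == 0.0)

    def test_x_strictly_increasing(self, stenosis_small_run):
        state, grid, _ = stenosis_small_run
        wall = wall_shear_stress(state, grid)
        assert np.all(np.diff(wall.x) > 0)
        assert np.all(wall.tau_wss >= 0)

    def test_poiseuille_wss(self, axisym_poiseuille_200x24):
        state, grid, bc = axisym_poiseuille_200x24
        wall = wall_shear_stress(state, grid)
        mid = np.abs(wall.x - 0.5e-3) < 0.25e-3
        exact = 4 * hf.FluidProperties().plasma_viscosity * bc.inlet_velocity_Vt / 50e-6
        assert np.mean(wall.tau_wss[mid]) == pytest.approx(exact, rel=0.03)


class TestSectionProfile:
    def test_uniform_inflow_region(self, stenosis_small_run):
        state, grid, bc = stenosis_small_run
        prof = section_profile(state, grid, -450e-6)
        # the inlet condition persists far upstream
        assert np.abs(prof.phi - bc.inlet_hematocrit_Ht).max() < 0.01 * 5

    def test_tube_exit_parabola(self, axisym_poiseuille_200x24):
        state, grid, bc = axisym_poiseuille_200x24
        prof = section_profile(state, grid, 0.98e-3)
        R, V = 50e-6, bc.inlet_velocity_Vt
        exact = 2 * V * (1 - (prof.y / R) ** 2)
        mask = exact > 0.05 * V
        err = np.abs(prof.u_axial_plasma[mask] - exact[mask]).max() / (2 * V)
        assert err < 0.02

    def test_out_of_domain_raises(self, stenosis_small_run):
        state, grid, _ = stenosis_small_run
        with pytest.raises(ValueError):
            section_profile(state, grid, 5e-3)

    def test_wall_endpoint_no_slip(self, stenosis_small_run):
        state, grid, _ = stenosis_small_run
        prof = section_profile(state, grid, 0.0)
        assert prof.u_axial_plasma[-1] == 0.0
        # wall ordinate at the throat: y(0)=hs up to the chord error of the
        # local cell width (~1 um on the 80x12 grid)
        assert prof.y[-1] == pytest.approx(25e-6, rel=0.06)


class TestRecirculation:
    def test_no_reversal_none(self):
        g = hf.build_uniform_grid(1e-3, 50e-6, 20, 6)
        st = _state(g, np.full(g.ncell, 0.1))
        assert recirculation_extent(st, g) is None

    def test_synthetic_pocket_located(self):
        g = hf.build_uniform_grid(1e-3, 50e-6, 100, 6)
        u = np.full(g.ncell, 0.1)
        wall_row = g.blocks[0].cells[:, -1]
        x = g.xc[wall_row]
        pocket = (x > 0.3e-3) & (x < 0.5e-3)
        u[wall_row[pocket]] = -0.05
        st = _state(g, u)
        ext = recirculation_extent(st, g)
        assert ext is not None
        x_sep, x_re = ext
        assert 0.28e-3 < x_sep < 0.32e-3
        assert 0.48e-3 < x_re < 0.52e-3

    def test_deterministic(self, stenosis_small_run):
        state, grid, _ = stenosis_small_run
        assert recirculation_extent(state, grid) == recirculation_extent(state, grid)


class TestLayerMetrics:
    def test_uniform_phi_no_layers(self):
        g = hf.build_uniform_grid(1e-3, 50e-6, 30, 6)
        st = _state(g, np.full(g.ncell, 0.1), phi=0.2)
        lm = layer_metrics(st, g, 0.2)
        assert lm.cell_free_extent is None
        assert lm.cell_rich_extent is None
        assert np.all(lm.cfl_thickness == 0.0)

    def test_synthetic_wall_layers(self):
        g = hf.build_uniform_grid(1e-3, 50e-6, 40, 8)
        cells = g.blocks[0].cells
        phi = np.full(g.ncell, 0.2)
        x = g.xc[cells[:, 0]]
        free_cols = (x > 0.2e-3) & (x < 0.4e-3)
        rich_cols = (x > 0.6e-3) & (x < 0.9e-3)
        phi[cells[free_cols, -1]] = 0.05     # wall-adjacent depletion
        phi[cells[free_cols, -2]] = 0.05     # two cells deep
        phi[cells[rich_cols, -1]] = 0.30
        st = _state(g, np.full(g.ncell, 0.1), phi=phi)
        lm = layer_metrics(st, g, 0.2)
        x0, x1, thick = lm.cell_free_extent
        assert 0.18e-3 < x0 < 0.24e-3 and 0.36e-3 < x1 < 0.42e-3
        assert thick == pytest.approx(2 * 50e-6 / 8, rel=1e-9)
        rx0, rx1, rthick = lm.cell_rich_extent
        assert 0.56e-3 < rx0 < 0.64e-3 and 0.86e-3 < rx1 < 0.92e-3
        assert rthick == pytest.approx(50e-6 / 8, rel=1e-9)

    def test_thresholds_configurable(self):
        g = hf.build_uniform_grid(1e-3, 50e-6, 20, 5)
        phi = np.full(g.ncell, 0.15)
        st = _state(g, np.full(g.ncell, 0.1), phi=phi)
        assert layer_metrics(st, g, 0.2).cell_free_extent is None
        strict = LayerThresholds(c_free=0.8, c_rich=1.2)
        assert layer_metrics(st, g, 0.2, strict).cell_free_extent is not None

    def test_pure_function(self, stenosis_small_run):
        state, grid, bc = stenosis_small_run
        a = layer_metrics(state, grid, bc.inlet_hematocrit_Ht)
        b = layer_metrics(state, grid, bc.inlet_hematocrit_Ht)
        np.testing.assert_array_equal(a.cfl_thickness, b.cfl_thickness)
        assert a.cell_free_extent == b.cell_free_extent


class TestOutputs:
    def test_vtk_round_trip(self, tmp_path):
        g = hf.build_uniform_grid(1e-3, 50e-6, 8, 4)
        rng = np.random.default_rng(5)
        q = rng.normal(0, 1, g.ncell)
        path = tmp_path / "f.vtk"
        write_vtk_structured(path, g, 0, {"q": q})
        pts, fields = read_vtk_structured(path)
        np.testing.assert_array_equal(pts[..., 0], g.blocks[0].X)
        np.testing.assert_array_equal(pts[..., 1], g.blocks[0].Y)
        np.testing.assert_array_equal(fields["q"], g.interpolate_to_nodes(q, 0))

    def test_write_outputs_schema(self, stenosis_small_run, tmp_path):
        state, grid, bc = stenosis_small_run
        prof = section_profile(state, grid, 0.0)
        files = write_outputs(state, grid, {"B": prof}, tmp_path,
                              Ht=bc.inlet_hematocrit_Ht)
        wall = pd.read_csv(tmp_path / "wall_shear_stress.csv")
        assert list(wall.columns) == ["x_m", "y_wall_m", "tau_wss_Pa"]
        sec = pd.read_csv(tmp_path / "section_B.csv")
        assert list(sec.columns) == ["y_m", "phi", "u_plasma_m_s", "u_rbc_m_s"]
        with open(tmp_path / "summary.yaml") as fh:
            summary = yaml.safe_load(fh)
        assert set(summary) == {
            "converged", "iterations", "residuals", "max_tau_wss_Pa",
            "x_at_max_tau_wss_m", "clipped_rbc_volume",
            "recirculation_extent_m", "cell_free_extent_m", "cell_rich_extent_m",
        }
        assert (tmp_path / "fields.vtk").exists()
        assert len(files) == 4
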