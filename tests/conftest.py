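"""Shared solved-case fixtures.

The expensive steady solves are session-scoped so that the unit,
post-processing and acceptance tests share one solution per case.
"""

import pytest

import hemoflow as hf


@pytest.fixture(scope="session")
def axisym_poiseuille_200x24():
    """Single-phase (vanishing-hematocrit) tube flow on the 200x24 grid."""
    grid = hf.build_uniform_grid(1e-3, 50e-6, 200, 24, mode="axisymmetric")
    bc = hf.BoundaryConditions(inlet_velocity_Vt=0.2, inlet_hematocrit_Ht=1e-6)
    params = hf.InteractionParams(enable_drag=False, enable_saffman=False,
                                  enable_spin=False)
    cfg = hf.SolverConfig(max_outer=3000, tol=1e-7, freeze_phi=True)
    state = hf.steady_solve(grid, bc, params=params, config=cfg)
    return state, grid, bc


@pytest.fixture(scope="session")
def planar_poiseuille_120x16():
    """Single-phase plane channel flow."""
    grid = hf.build_uniform_grid(1e-3, 50e-6, 120, 16, mode="planar")
    bc = hf.BoundaryConditions(inlet_velocity_Vt=0.2, inlet_hematocrit_Ht=1e-6)
    params = hf.InteractionParams(enable_drag=False, enable_saffman=False,
                                  enable_spin=False)
    cfg = hf.SolverConfig(max_outer=3000, tol=1e-7, freeze_phi=True)
    state = hf.steady_solve(grid, bc, params=params, config=cfg)
    return state, grid, bc


@pytest.fixture(scope="session")
def stenosis_base_run():
    """Two-phase baseline: Vt = 0.2 m/s, Ht = 20 %, tight convergence."""
    grid = hf.build_stenosis_grid(hf.StenosisGeometry(), 160, 20)
    bc = hf.BoundaryConditions(inlet_velocity_Vt=0.2, inlet_hematocrit_Ht=0.20)
    cfg = hf.SolverConfig(max_outer=3000, tol=1e-7)
    state = hf.steady_solve(grid, bc, config=cfg)
    return state, grid, bc


@pytest.fixture(scope="session")
def expansion_run(tmp_path_factory):
    """Sudden-expansion validation at the default desk-scale resolution."""
    from hemoflow.experiments import run_expansion_validation

    out = tmp_path_factory.mktemp("expansion")
    return run_expansion_validation(out_dir=str(out))


@pytest.fixture(scope="session")
def sweep_report(tmp_path_factory):
    """The full stenosis run matrix with trend verdicts."""
    from hemoflow.experiments import SweepSpec, run_stenosis_sweep

    out = tmp_path_factory.mktemp("sweep")
    return run_stenosis_sweep(SweepSpec(out_dir=str(out)))


@pytest.fixture(scope="session")
def stenosis_small_run():
    """Two-phase stenosis on a small grid for quick structural tests."""
    grid = hf.build_stenosis_grid(hf.StenosisGeometry(), 80, 12)
    bc = hf.BoundaryConditions(inlet_velocity_Vt=0.2, inlet_hematocrit_Ht=0.20)
    cfg = hf.SolverConfig(max_outer=1500, tol=1e-5)
    state = hf.steady_solve(grid, bc, config=cfg)
    return state, grid, bc
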