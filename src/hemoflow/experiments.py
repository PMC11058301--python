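"""Scripted desk-scale studies: validation, parameter sweeps, verification.

Three instruments:

* the sudden-expansion validation (uniform inlet at 0.833 m/s, 20 %
  hematocrit, transverse gravity) checking the qualitative benchmark
  features — a downstream wall-adjacent cell-free layer and a corner
  recirculation;
* the stenosis sweeps over inlet velocity amplitude Vt (0.1/0.2/0.4/0.8
  m/s at Ht = 20 %) and inlet hematocrit Ht (10/20/40 % at Vt = 0.2 m/s)
  with trend verdicts on the maximum wall shear stress and the
  recirculation length;
* an analytic verification suite (Poiseuille limits, rheology limits,
  interphase-force closure) and a mesh-independence study mirroring the
  refinement procedure a practitioner would run before trusting a grid.

The default grids are desk-scale (thousands of cells, not the ~1.6e5
nodes of production CFD meshes); the mesh-independence study is the
instrument for judging their adequacy.  The direction of the maximum wall
shear stress with hematocrit is reported but deliberately not asserted:
published statements on its direction disagree, and this package simply records
its own computed direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .config import CaseConfig, default_expansion_config, default_stenosis_config
from .geometry import StenosisGeometry
from .interaction import InteractionParams, total_interaction
from .mesh import build_stenosis_grid, build_uniform_grid
from .postprocess import (
    layer_metrics,
    recirculation_extent,
    section_profile,
    wall_shear_stress,
    write_outputs,
)
from .properties import FluidProperties
from .rheology import mu_zero, rbc_viscosity
from .solver import BoundaryConditions, SolverConfig, steady_solve

__all__ = [
    "SweepSpec",
    "TrendReport",
    "run_case",
    "run_expansion_validation",
    "run_stenosis_sweep",
    "run_verification_suite",
    "mesh_independence_study",
]

#: the reference study's run matrix
DEFAULT_VT_SWEEP = (0.1, 0.2, 0.4, 0.8)
DEFAULT_HT_SWEEP = (0.10, 0.20, 0.40)
BASE_VT = 0.2
BASE_HT = 0.20
#: desk-scale grids: the velocity sweep uses 160 axial cells (~3.4 um
#: spacing at the throat, enough to localize the wall-shear peak at the
#: lowest Vt); the hematocrit sweep uses 120 (the deep depletion zones of
#: the 10 % case are iteration-stable there).  Each sweep carries its own
#: baseline so trends compare like with like.
VT_SWEEP_GRID = (160, 20)
HT_SWEEP_GRID = (120, 20)


def _default_runs():
    return tuple(
        [(v, BASE_HT) + VT_SWEEP_GRID for v in DEFAULT_VT_SWEEP]
        + [(BASE_VT, h) + HT_SWEEP_GRID for h in DEFAULT_HT_SWEEP]
    )


@dataclass
class SweepSpec:
    """A list of (Vt, Ht, nx, ny) runs."""

    case_id: str = "stenosis"
    runs: tuple = field(default_factory=_default_runs)
    out_dir: str = "out/sweep"
    tol: float = 1e-5
    max_outer: int = 2500


@dataclass
class TrendReport:
    """Per-run summaries plus monotonicity verdicts."""

    runs: list
    verdicts: dict
    grid: tuple
    out_dir: str | None = None

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"grid": list(self.grid), "verdicts": self.verdicts, "runs": self.runs},
                fh, sort_keys=False,
            )


def run_case(cfg: CaseConfig, write: bool = True):
    """Solve one configured case; optionally write the standard outputs.

    Returns ``(state, grid, summary_dict)``.
    """
    grid = cfg.build_grid()
    state = steady_solve(grid, cfg.bc, cfg.props, cfg.coeffs, cfg.params, cfg.solver)
    wall = wall_shear_stress(state, grid, cfg.props)
    imax = int(np.argmax(wall.tau_wss))
    rec = recirculation_extent(state, grid)
    lm = layer_metrics(state, grid, cfg.bc.inlet_hematocrit_Ht)
    summary = {
        "Vt": cfg.bc.inlet_velocity_Vt,
        "Ht": cfg.bc.inlet_hematocrit_Ht,
        "converged": bool(state.converged),
        "iterations": int(state.iterations),
        "max_tau_wss_Pa": float(wall.tau_wss[imax]),
        "x_at_max_tau_wss_m": float(wall.x[imax]),
        "recirc_extent_m": [float(v) for v in rec] if rec else None,
        "recirc_length_m": float(rec[1] - rec[0]) if rec else 0.0,
        "cell_free_extent_m": list(lm.cell_free_extent) if lm.cell_free_extent else None,
        "cell_rich_extent_m": list(lm.cell_rich_extent) if lm.cell_rich_extent else None,
    }
    if write:
        sections = {}
        if cfg.case == "stenosis":
            for label, xs in (("A", -30e-6), ("B", 0.0), ("C", 30e-6)):
                sections[label] = section_profile(state, grid, xs)
        else:
            sections["x20um"] = section_profile(state, grid, 0.02e-3)
        write_outputs(state, grid, sections, cfg.out_dir, cfg.props,
                      Ht=cfg.bc.inlet_hematocrit_Ht)
        with open(Path(cfg.out_dir) / "run_summary.yaml", "w") as fh:
            yaml.safe_dump(summary, fh, sort_keys=True)
    return state, grid, summary


def run_expansion_validation(
    resolution: tuple[int, int, int] | None = None,
    out_dir: str = "out/expansion",
    tol: float = 1e-5,
    max_outer: int = 4000,
) -> TrendReport:
    """Sudden-expansion benchmark with gravity; checks the two hallmark
    features (downstream cell-free layer, corner recirculation)."""
    cfg = default_expansion_config(out=out_dir)
    if resolution is not None:
        nx_up, ny_up, nx_down = resolution
        cfg.grid_nx, cfg.grid_ny, cfg.grid_nx_down = nx_up, ny_up, nx_down
    cfg.solver = SolverConfig(tol=tol, max_outer=max_outer)
    state, grid, summary = run_case(cfg)
    prof = section_profile(state, grid, 0.02e-3)
    lm = layer_metrics(state, grid, cfg.bc.inlet_hematocrit_Ht, block=1)
    rec = recirculation_extent(state, grid, block=1)
    # RBC accumulation near the corner: maximum phi in the step region
    blk = grid.blocks[1]
    near = grid.xc[blk.cells] < 0.3e-3
    phi_corner_max = float(state.phi[blk.cells][near].max())
    verdicts = {
        "converged": bool(state.converged),
        "cell_free_layer_downstream": lm.cell_free_extent is not None,
        "corner_recirculation": rec is not None and rec[0] < 0.5e-3,
        "corner_phi_accumulation": phi_corner_max > cfg.bc.inlet_hematocrit_Ht,
        "phi_corner_max": phi_corner_max,
    }
    report = TrendReport(
        runs=[summary | {"phi_profile_x0.02mm": {
            "y_m": prof.y.tolist(), "phi": prof.phi.tolist()}}],
        verdicts=verdicts,
        grid=(cfg.grid_nx, cfg.grid_ny, cfg.grid_nx_down),
        out_dir=out_dir,
    )
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    report.save(Path(out_dir) / "report.yaml")
    return report


def _strictly_increasing(vals) -> bool:
    return all(b > a for a, b in zip(vals, vals[1:]))


def run_stenosis_sweep(spec: SweepSpec | None = None) -> TrendReport:
    """Execute the stenosis run matrix and evaluate the trend checks."""
    spec = spec or SweepSpec()
    summaries = []
    for Vt, Ht, nx, ny in spec.runs:
        cfg = default_stenosis_config(
            Vt=Vt, Ht=Ht, out=str(Path(spec.out_dir) / f"Vt{Vt}_Ht{Ht}_{nx}x{ny}"))
        cfg.grid_nx, cfg.grid_ny = nx, ny
        cfg.solver = SolverConfig(tol=spec.tol, max_outer=spec.max_outer)
        _, _, summary = run_case(cfg)
        summary["grid"] = [nx, ny]
        summaries.append(summary)

    def _largest_same_grid_group(runs, key):
        groups: dict = {}
        for s in runs:
            groups.setdefault(tuple(s["grid"]), []).append(s)
        if not groups:
            return []
        return sorted(max(groups.values(), key=len), key=key)

    vt_runs = _largest_same_grid_group(
        [s for s in summaries if s["Ht"] == BASE_HT], key=lambda s: s["Vt"])
    ht_runs = _largest_same_grid_group(
        [s for s in summaries if s["Vt"] == BASE_VT], key=lambda s: s["Ht"])
    taus_vt = [s["max_tau_wss_Pa"] for s in vt_runs]
    recs_vt = [s["recirc_length_m"] for s in vt_runs]
    taus_ht = [s["max_tau_wss_Pa"] for s in ht_runs]
    if _strictly_increasing(taus_ht):
        ht_direction = "increasing"
    elif _strictly_increasing(taus_ht[::-1]):
        ht_direction = "decreasing"
    else:
        ht_direction = "non-monotonic"
    verdicts = {
        "all_converged": all(s["converged"] for s in summaries),
        "max_tau_increases_with_Vt": _strictly_increasing(taus_vt),
        "recirc_length_increases_with_Vt": _strictly_increasing(recs_vt),
        "max_tau_location_upstream_all": all(
            s["x_at_max_tau_wss_m"] < 0.0 for s in summaries
        ),
        # reported, not asserted: published statements on this trend
        # conflict with each other
        "max_tau_vs_Ht_direction": ht_direction,
    }
    grids = [list(gr) for gr in sorted({tuple(s["grid"]) for s in summaries})]
    report = TrendReport(runs=summaries, verdicts=verdicts,
                         grid=grids, out_dir=spec.out_dir)
    Path(spec.out_dir).mkdir(parents=True, exist_ok=True)
    report.save(Path(spec.out_dir) / "report.yaml")
    return report


def _poiseuille_case(mode: str, nx: int, ny: int, tol: float = 1e-7):
    R, L, Vt = 50e-6, 1e-3, 0.2
    grid = build_uniform_grid(L, R, nx, ny, mode=mode)
    bc = BoundaryConditions(inlet_velocity_Vt=Vt, inlet_hematocrit_Ht=1e-6)
    params = InteractionParams(enable_drag=False, enable_saffman=False, enable_spin=False)
    cfg = SolverConfig(max_outer=4000, tol=tol, freeze_phi=True)
    state = steady_solve(grid, bc, params=params, config=cfg)
    blk = grid.blocks[0]
    exit_ids = blk.cells[-1, :]
    u_centre = float(state.vp[exit_ids[0], 0])
    ratio = u_centre / Vt
    wall = wall_shear_stress(state, grid)
    mid = np.abs(wall.x - L / 2) < L / 4
    tau_mid = float(np.mean(wall.tau_wss[mid]))
    mu = FluidProperties().plasma_viscosity
    tau_exact = 4 * mu * Vt / R if mode == "axisymmetric" else 3 * mu * Vt / R
    ratio_exact = 2.0 if mode == "axisymmetric" else 1.5
    return {
        "mode": mode, "nx": nx, "ny": ny,
        "converged": bool(state.converged),
        "centerline_ratio": ratio,
        "centerline_ratio_error": abs(ratio / ratio_exact - 1.0),
        "tau_wall_Pa": tau_mid,
        "tau_exact_Pa": tau_exact,
        "tau_error": abs(tau_mid / tau_exact - 1.0),
    }


def run_verification_suite(out_dir: str = "out/verify", fast: bool = False) -> dict:
    """Analytic oracles: Poiseuille limits, rheology limits, force closure.

    ``fast`` shrinks the grid ladder for quick smoke runs.
    """
    levels = [(50, 6), (100, 12)] if fast else [(50, 6), (100, 12), (200, 24)]
    report: dict = {"poiseuille": {}}
    for mode in ("axisymmetric", "planar"):
        rows = [_poiseuille_case(mode, nx, ny) for nx, ny in levels]
        errs = [r["centerline_ratio_error"] for r in rows]
        hs = [1.0 / ny for _, ny in levels]
        orders = [
            float(np.log(errs[i] / errs[i + 1]) / np.log(hs[i] / hs[i + 1]))
            if errs[i + 1] > 0 else float("inf")
            for i in range(len(errs) - 1)
        ]
        report["poiseuille"][mode] = {
            "levels": rows,
            "errors_decrease": all(b < a for a, b in zip(errs, errs[1:])),
            "observed_orders": orders,
        }

    # rheology limits
    phis = np.linspace(0.05, 0.6, 12)
    zero_shear = rbc_viscosity(phis, np.zeros_like(phis))
    expect = 0.5 * mu_zero(phis, floor=None) * (1 + phis)
    gd = np.logspace(-2, 6, 30)
    # shear-thinning holds where mu0 > muinf (the fits cross near phi~0.11)
    mono = all(
        bool(np.all(np.diff(rbc_viscosity(np.full_like(gd, p), gd))
                    <= 1e-12 * rbc_viscosity(p, 0.0)))
        for p in (0.15, 0.3, 0.45, 0.6)
    )
    report["rheology"] = {
        "zero_shear_limit_max_rel_err": float(
            np.max(np.abs(zero_shear - np.maximum(expect, 9.6e-5)) / expect)
        ),
        "shear_thinning_monotone": mono,
    }

    # interphase-force closure: the plasma gain equals the RBC loss by the
    # sign contract, so the pairwise sum vanishes identically
    rng = np.random.default_rng(0)
    n = 64
    from .fields import TensorField2D

    phi = rng.uniform(0.05, 0.6, n)
    vp = rng.normal(0, 0.1, (n, 2))
    vr = rng.normal(0, 0.1, (n, 2))
    D = TensorField2D(xx=rng.normal(0, 100, n), xy=rng.normal(0, 100, n),
                      yy=rng.normal(0, 100, n))
    w = rng.normal(0, 50, n)
    W = TensorField2D(xx=np.zeros(n), xy=w, yy=np.zeros(n), yx=-w)
    Wr = TensorField2D(xx=np.zeros(n), xy=-w, yy=np.zeros(n), yx=w)
    fI = total_interaction(phi, vp, vr, D, W, Wr)
    closure = float(np.max(np.abs(fI + (-fI))))
    report["interaction_closure_residual"] = closure

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "verification.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    return report


def mesh_independence_study(
    case: str = "stenosis",
    resolutions=((80, 14), (120, 20), (160, 20)),
    x_section: float = 20e-6,
    out_dir: str = "out/mesh_study",
    Vt: float = BASE_VT,
    Ht: float = BASE_HT,
    tol: float = 1e-5,
) -> dict:
    """Profile-based grid refinement study at a fixed cross-section.

    Solves the case on each resolution, interpolates phi(y) at
    ``x_section`` onto a common sampling, and tabulates pairwise maximum
    differences (relative to the finest-grid profile scale).  The report
    flags the coarsest resolution within 2 % of the finest.
    """
    if case != "stenosis":
        raise ValueError("the mesh study is defined for the stenosis case")
    geom = StenosisGeometry()
    profiles = []
    for nx, ny in resolutions:
        grid = build_stenosis_grid(geom, nx, ny)
        bc = BoundaryConditions(inlet_velocity_Vt=Vt, inlet_hematocrit_Ht=Ht)
        state = steady_solve(grid, bc, config=SolverConfig(tol=tol, max_outer=2500))
        prof = section_profile(state, grid, x_section, n_samples=64)
        profiles.append(prof.phi)
    profiles = np.asarray(profiles)
    scale = float(np.max(np.abs(profiles[-1])))
    n = len(resolutions)
    table = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            table[i, j] = float(np.max(np.abs(profiles[i] - profiles[j]))) / scale
    adequate = None
    for i in range(n):
        if table[i, -1] < 0.02:
            adequate = list(resolutions[i])
            break
    report = {
        "x_section_m": float(x_section),
        "resolutions": [list(r) for r in resolutions],
        "pairwise_max_rel_diff": table.tolist(),
        "coarsest_within_2pct_of_finest": adequate,
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "mesh_study.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    return report
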