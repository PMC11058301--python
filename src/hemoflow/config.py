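"""Human-readable case configuration (YAML) and object assembly.

A case file has up to seven blocks — geometry, fluid, rheology,
interaction, bc, solver, output — each optional; omitted keys fall back
to the package defaults (which are the baseline stenosed-microvessel
study conditions).  Example::

    case: stenosis
    geometry: {H: 50e-6, hs: 25e-6, Ls: 70e-6, L_up: 500e-6, L_down: 500e-6}
    bc: {Vt: 0.2, Ht: 0.2}
    grid: {nx: 120, ny: 20}
    solver: {tol: 1.0e-5, max_outer: 2000}
    output: {dir: out}
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .geometry import ExpansionGeometry, StenosisGeometry
from .interaction import InteractionParams
from .mesh import (
    GridClustering,
    StructuredGrid,
    build_expansion_grid,
    build_stenosis_grid,
)
from .properties import FluidProperties, RheologyCoefficients
from .solver import BoundaryConditions, SolverConfig

__all__ = ["CaseConfig", "load_config", "default_stenosis_config", "default_expansion_config"]


@dataclass
class CaseConfig:
    """Fully resolved description of one run."""

    case: str  # "stenosis" | "expansion"
    geometry: StenosisGeometry | ExpansionGeometry
    props: FluidProperties
    coeffs: RheologyCoefficients
    params: InteractionParams
    bc: BoundaryConditions
    solver: SolverConfig
    grid_nx: int
    grid_ny: int
    grid_nx_down: int  # expansion only
    clustering: GridClustering
    out_dir: str

    def build_grid(self) -> StructuredGrid:
        if self.case == "stenosis":
            return build_stenosis_grid(self.geometry, self.grid_nx, self.grid_ny,
                                       self.clustering)
        return build_expansion_grid(self.geometry, self.grid_nx, self.grid_ny,
                                    self.grid_nx_down)


def _filtered(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**{k: v for k, v in d.items()})


def _assemble(raw: dict, overrides: dict | None = None) -> CaseConfig:
    raw = dict(raw or {})
    overrides = overrides or {}
    case = raw.get("case", "stenosis")
    if case not in ("stenosis", "expansion"):
        raise ValueError("case must be 'stenosis' or 'expansion'")

    geo_d = {k: float(v) for k, v in (raw.get("geometry") or {}).items()
             if k != "mode"}
    if "mode" in (raw.get("geometry") or {}):
        geo_d["mode"] = raw["geometry"]["mode"]
    geometry = _filtered(StenosisGeometry if case == "stenosis" else ExpansionGeometry, geo_d)

    props = _filtered(FluidProperties, {k: float(v) for k, v in (raw.get("fluid") or {}).items()})
    rhe = dict(raw.get("rheology") or {})
    for key in ("mu0_poly", "muinf_poly"):
        if key in rhe:
            rhe[key] = tuple(float(v) for v in rhe[key])
    coeffs = _filtered(RheologyCoefficients, rhe)
    params = _filtered(InteractionParams, dict(raw.get("interaction") or {}))

    bc_d = dict(raw.get("bc") or {})
    bc_map = {"Vt": "inlet_velocity_Vt", "Ht": "inlet_hematocrit_Ht"}
    bc_d = {bc_map.get(k, k): v for k, v in bc_d.items()}
    bc_d.setdefault("inlet_velocity_Vt", 0.2)
    bc_d.setdefault("inlet_hematocrit_Ht", 0.2)
    if "Vt" in overrides and overrides["Vt"] is not None:
        bc_d["inlet_velocity_Vt"] = overrides["Vt"]
    if "Ht" in overrides and overrides["Ht"] is not None:
        bc_d["inlet_hematocrit_Ht"] = overrides["Ht"]
    if "gravity" in bc_d:
        bc_d["gravity"] = tuple(float(v) for v in bc_d["gravity"])
    bc = _filtered(BoundaryConditions, bc_d)

    solver = _filtered(SolverConfig, dict(raw.get("solver") or {}))

    grid_d = dict(raw.get("grid") or {})
    nx = int(overrides.get("nx") or grid_d.get("nx", 120))
    ny = int(overrides.get("ny") or grid_d.get("ny", 20))
    nx_down = int(grid_d.get("nx_down", 2 * nx))
    cl_d = {k: float(v) for k, v in (grid_d.get("clustering") or {}).items()}
    clustering = _filtered(GridClustering, cl_d)

    out_dir = overrides.get("out") or (raw.get("output") or {}).get("dir", "out")
    return CaseConfig(
        case=case, geometry=geometry, props=props, coeffs=coeffs, params=params,
        bc=bc, solver=solver, grid_nx=nx, grid_ny=ny, grid_nx_down=nx_down,
        clustering=clustering, out_dir=str(out_dir),
    )


def load_config(path, **overrides) -> CaseConfig:
    """Load a YAML case file; keyword overrides (Vt, Ht, nx, ny, out) win."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _assemble(raw, overrides)


def default_stenosis_config(**overrides) -> CaseConfig:
    """Baseline stenosed-microvessel case: Vt = 0.2 m/s, Ht = 20 %."""
    return _assemble({"case": "stenosis"}, overrides)


def default_expansion_config(**overrides) -> CaseConfig:
    """Sudden-expansion validation case: Vt = 0.833 m/s, Ht = 20 %, with
    transverse gravity emulating the horizontal channel of the benchmark."""
    raw = {
        "case": "expansion",
        "bc": {"Vt": 0.833, "Ht": 0.2, "gravity": (0.0, -9.81)},
        # the downstream cell-free layer is thin; ny = 16 (3.1 um transverse
        # spacing) is the coarsest level that resolves its depletion
        "grid": {"nx": 64, "ny": 16, "nx_down": 140},
    }
    return _assemble(raw, overrides)
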