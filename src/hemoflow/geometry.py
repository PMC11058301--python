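"""Parametric case geometries: cosine stenosis and sudden expansion.

Both cases are solved on half-domains.  The stenosed microvessel is
axisymmetric: ``y`` is the radial coordinate from the axis to the wall and
the wall radius follows a cosine bump,

    y(x) = (H + hs)/2 - (H - hs)/2 * cos(2 pi x / Ls),   |x| <= Ls/2,

with y = H outside the stenosed segment.  The origin sits at the point of
maximum stenosis, x increasing downstream.  The sudden-expansion channel is
planar with a symmetry plane at y = 0; the origin sits at the expansion
corner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StenosisGeometry",
    "ExpansionGeometry",
    "stenosis_wall_radius",
    "dimensionless_ratios",
]


@dataclass(frozen=True)
class StenosisGeometry:
    """Cosine-profile stenosed microvessel (half-domain).

    Defaults: H = 50 um unobstructed radius, hs = 25 um throat radius,
    Ls = 70 um stenosis length, 500 um straight entry and exit runs,
    axisymmetric.  Derived ratios: eta_h = hs/H, eta_L = Ls/H.
    """

    H: float = 50e-6
    hs: float = 25e-6
    Ls: float = 70e-6
    L_up: float = 500e-6
    L_down: float = 500e-6
    mode: str = "axisymmetric"  # "planar" | "axisymmetric"

    def __post_init__(self) -> None:
        if not (0.0 < self.hs <= self.H):
            # hs == H degenerates to an unobstructed tube, useful for checks
            raise ValueError("require 0 < hs <= H")
        if self.Ls <= 0.0 or self.L_up <= 0.0 or self.L_down <= 0.0:
            raise ValueError("lengths must be positive")
        if self.mode not in ("planar", "axisymmetric"):
            raise ValueError("mode must be 'planar' or 'axisymmetric'")

    @property
    def eta_h(self) -> float:
        return self.hs / self.H

    @property
    def eta_L(self) -> float:
        return self.Ls / self.H

    def wall_radius(self, x) -> np.ndarray:
        return stenosis_wall_radius(x, self)


@dataclass(frozen=True)
class ExpansionGeometry:
    """Planar channel with a sudden expansion (half-domain).

    Half-heights: the full channel is 100 um high upstream and 200 um high
    downstream; the symmetric half-model spans 50 um / 100 um.  The
    expansion corner sits at x = 0 with a 1 mm upstream and 2 mm downstream
    run.
    """

    h_up: float = 50e-6
    h_down: float = 100e-6
    L_up: float = 1e-3
    L_down: float = 2e-3
    mode: str = "planar"

    def __post_init__(self) -> None:
        if not (self.h_down > self.h_up > 0.0):
            raise ValueError("require h_down > h_up > 0")
        if self.L_up <= 0.0 or self.L_down <= 0.0:
            raise ValueError("lengths must be positive")
        if self.mode != "planar":
            raise ValueError("the sudden-expansion case is planar")


def stenosis_wall_radius(x, geom: StenosisGeometry) -> np.ndarray:
    """Wall ordinate y(x) of the cosine stenosis, m.

    Piecewise: the cosine profile inside |x| <= Ls/2, the unobstructed
    radius H outside; continuous at the junctions.  ``x`` outside
    [-L_up, L_down] raises.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < -geom.L_up - 1e-15) or np.any(x_arr > geom.L_down + 1e-15):
        raise ValueError("x outside the meshed domain [-L_up, L_down]")
    y = np.where(
        np.abs(x_arr) <= geom.Ls / 2.0,
        0.5 * (geom.H + geom.hs)
        - 0.5 * (geom.H - geom.hs) * np.cos(2.0 * np.pi * x_arr / geom.Ls),
        geom.H,
    )
    return y if y.ndim else float(y)


def dimensionless_ratios(geom: StenosisGeometry) -> tuple[float, float]:
    """Stenosed-height ratio eta_h = hs/H and stenosed-length ratio eta_L = Ls/H."""
    return geom.eta_h, geom.eta_L
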