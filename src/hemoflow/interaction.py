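"""Interphase momentum exchange between plasma and the RBC phase.

The force density (N/m^3) exchanged between the phases is the sum of a
hindered Stokes drag, the Saffman shear-lift, and a spin-lift:

    f_I = (9 mu_p / (2 a^2)) f(phi) (v_r - v_p)
        + (3*6.46 sqrt(rho_p mu_p) / (4 pi a)) phi [2 tr(D_p^2)]^(-1/4) D_p (v_r - v_p)
        + (3/4) rho_p phi (W_r - W_p) (v_r - v_p)

with the hindrance function f(phi) = phi (1 + 6.55 phi) and a the RBC size.
By sign convention ``f_I`` is added to the plasma momentum balance and
subtracted from the RBC momentum balance, so the exchange closes pairwise
(Newton's third law) in every cell.

The Saffman prefactor diverges as the plasma shear rate vanishes; the shear
rate is floored at ``InteractionParams.shear_floor`` which keeps the term
bounded and continuous (the tensor-vector product D_p (v_r - v_p) already
vanishes with D_p, so the regularization only matters at small but nonzero
strain rates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import TensorField2D, VectorField2D
from .properties import FluidProperties
from .rheology import generalized_shear_rate

__all__ = [
    "InteractionParams",
    "hindrance",
    "drag_force",
    "saffman_lift",
    "spin_lift",
    "total_interaction",
]


@dataclass(frozen=True)
class InteractionParams:
    """Coefficients and enable flags of the interphase force terms.

    ``shear_floor`` (1/s) regularizes the Saffman singularity at vanishing
    plasma shear rate.  Virtual-mass, Basset and surface-tension forces are
    deliberately not implemented; the flags cover the three modelled terms.
    """

    saffman_coeff: float = 6.46
    spin_coeff: float = 0.75
    shear_floor: float = 1e-3
    enable_drag: bool = True
    enable_saffman: bool = True
    enable_spin: bool = True

    def __post_init__(self) -> None:
        if self.saffman_coeff <= 0.0 or self.spin_coeff <= 0.0:
            raise ValueError("lift coefficients must be positive")
        if self.shear_floor <= 0.0:
            raise ValueError("shear_floor must be positive")


def hindrance(phi) -> np.ndarray:
    """Hindrance function f(phi) = phi (1 + 6.55 phi) scaling the drag."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0.0) or np.any(phi > 1.0):
        raise ValueError("volume fraction phi must lie in [0, 1]")
    return phi * (1.0 + 6.55 * phi)


def _slip(vp: VectorField2D, vr: VectorField2D) -> np.ndarray:
    return np.asarray(vr, dtype=float) - np.asarray(vp, dtype=float)


def drag_force(
    phi,
    vp: VectorField2D,
    vr: VectorField2D,
    props: FluidProperties = FluidProperties(),
) -> VectorField2D:
    """Hindered Stokes drag on the plasma: (9 mu_p / 2 a^2) f(phi) (v_r - v_p)."""
    slip = _slip(vp, vr)
    coeff = drag_coefficient(phi, props)
    return coeff[:, None] * slip if coeff.ndim else coeff * slip


def drag_coefficient(phi, props: FluidProperties = FluidProperties()) -> np.ndarray:
    """Drag coefficient K (N s / m^4) so that the drag force is K (v_r - v_p)."""
    return 9.0 * props.plasma_viscosity / (2.0 * props.rbc_size_a**2) * hindrance(phi)


def saffman_lift(
    phi,
    Dp: TensorField2D,
    vp: VectorField2D,
    vr: VectorField2D,
    props: FluidProperties = FluidProperties(),
    params: InteractionParams = InteractionParams(),
) -> VectorField2D:
    """Saffman shear-lift force density on the plasma side, N/m^3."""
    phi = np.asarray(phi, dtype=float)
    slip = _slip(vp, vr)
    gdot = np.maximum(generalized_shear_rate(Dp), params.shear_floor)
    pref = (
        3.0
        * params.saffman_coeff
        * np.sqrt(props.plasma_density * props.plasma_viscosity)
        / (4.0 * np.pi * props.rbc_size_a)
    )
    scale = pref * phi * gdot ** (-0.5)  # [2 tr(Dp^2)]^(-1/4) == gdot^(-1/2)
    return scale[:, None] * Dp.dot_vec(slip)


def spin_lift(
    phi,
    Wp: TensorField2D,
    Wr: TensorField2D,
    vp: VectorField2D,
    vr: VectorField2D,
    props: FluidProperties = FluidProperties(),
    params: InteractionParams = InteractionParams(),
    *,
    antisym_tol: float = 1e-9,
) -> VectorField2D:
    """Spin-lift force density (3/4) rho_p phi (W_r - W_p)(v_r - v_p), N/m^3.

    In 2D the product of an antisymmetric tensor with the slip vector is
    perpendicular to the slip.  Raises if either spin tensor is not
    antisymmetric within ``antisym_tol`` (relative).
    """
    Wp.assert_antisymmetric(antisym_tol)
    Wr.assert_antisymmetric(antisym_tol)
    phi = np.asarray(phi, dtype=float)
    slip = _slip(vp, vr)
    dW_xy = Wr.xy - Wp.xy
    prod = np.empty_like(slip)
    prod[:, 0] = dW_xy * slip[:, 1]
    prod[:, 1] = -dW_xy * slip[:, 0]
    return (params.spin_coeff * props.plasma_density * phi)[:, None] * prod


def total_interaction(
    phi,
    vp: VectorField2D,
    vr: VectorField2D,
    Dp: TensorField2D,
    Wp: TensorField2D,
    Wr: TensorField2D,
    props: FluidProperties = FluidProperties(),
    params: InteractionParams = InteractionParams(),
) -> VectorField2D:
    """Sum of the enabled interphase force terms, N/m^3.

    Sign contract: the returned field is ADDED to the plasma momentum
    residual and SUBTRACTED from the RBC momentum residual.
    """
    phi = np.asarray(phi, dtype=float)
    out = np.zeros((phi.shape[0], 2))
    if params.enable_drag:
        out += drag_force(phi, vp, vr, props)
    if params.enable_saffman:
        out += saffman_lift(phi, Dp, vp, vr, props, params)
    if params.enable_spin:
        out += spin_lift(phi, Wp, Wr, vp, vr, props, params)
    return out
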