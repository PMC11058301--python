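"""Constitutive laws of the two phases.

Plasma is Newtonian.  The RBC phase is shear-thinning and hematocrit
dependent:

    mu_r = 1/2 [ mu_inf + (mu_0 - mu_inf) (1 + ln(1 + k*gdot)) / (1 + k*gdot) ] (1 + phi)

with mu_0(phi), mu_inf(phi) quadratic fits (in cP) and the generalized shear
rate gdot = sqrt(2 tr(D^2)) taken from the RBC strain-rate tensor.  Phase
stresses share a single hydrodynamic pressure weighted by the phase volume
fraction:

    T_p = -p (1-phi) I + 2 mu_p (1-phi) D_p
    T_r = -p phi I     + 2 mu_r phi     D_r

(the plasma second-viscosity term vanishes with tr(D_p)=0; the RBC second
viscosity lambda_r has no established value and defaults to zero).
"""

from __future__ import annotations

import numpy as np

from .fields import TensorField2D
from .properties import DEFAULT_VISCOSITY_FLOOR, FluidProperties, RheologyCoefficients

__all__ = [
    "mu_zero",
    "mu_inf",
    "generalized_shear_rate",
    "rbc_viscosity",
    "plasma_viscous_stress",
    "plasma_stress",
    "rbc_stress",
]


def _check_phi(phi) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0.0) or np.any(phi > 1.0):
        raise ValueError("volume fraction phi must lie in [0, 1]")
    return phi


def _poly(coeffs: tuple[float, float, float], phi: np.ndarray) -> np.ndarray:
    a, b, c = coeffs
    return (a * phi + b) * phi + c


def mu_zero(
    phi,
    coeffs: RheologyCoefficients = RheologyCoefficients(),
    *,
    floor: float | None = DEFAULT_VISCOSITY_FLOOR,
):
    """Zero-shear RBC viscosity mu_0(phi) in Pa*s.

    ``floor=None`` returns the raw polynomial (which is slightly negative
    for phi below ~0.0023, a known artefact of the fit).
    """
    phi = _check_phi(phi)
    out = _poly(coeffs.mu0_poly, phi) * coeffs.output_unit_scale
    if floor is not None:
        out = np.maximum(out, floor)
    return out


def mu_inf(
    phi,
    coeffs: RheologyCoefficients = RheologyCoefficients(),
    *,
    floor: float | None = DEFAULT_VISCOSITY_FLOOR,
):
    """Infinite-shear RBC viscosity mu_inf(phi) in Pa*s."""
    phi = _check_phi(phi)
    out = _poly(coeffs.muinf_poly, phi) * coeffs.output_unit_scale
    if floor is not None:
        out = np.maximum(out, floor)
    return out


def generalized_shear_rate(D: TensorField2D) -> np.ndarray:
    """Scalar shear-rate invariant sqrt(2 tr(D^2)) >= 0, 1/s.

    ``D`` must be a symmetric strain-rate field; in axisymmetric mode the
    hoop component enters the invariant.
    """
    tr_D2 = D.xx**2 + D.yy**2 + 2.0 * D.xy**2
    if D.tt is not None:
        tr_D2 = tr_D2 + D.tt**2
    return np.sqrt(2.0 * tr_D2)


def rbc_viscosity(
    phi,
    gamma_dot,
    coeffs: RheologyCoefficients = RheologyCoefficients(),
    *,
    floor: float | None = DEFAULT_VISCOSITY_FLOOR,
):
    """Shear-thinning, hematocrit-dependent RBC-phase viscosity, Pa*s.

    Monotone non-increasing in ``gamma_dot``; brackets between
    mu_inf(phi)(1+phi)/2 (high shear) and mu_0(phi)(1+phi)/2 (zero shear).
    """
    phi = _check_phi(phi)
    gamma_dot = np.asarray(gamma_dot, dtype=float)
    if np.any(gamma_dot < 0.0):
        raise ValueError("gamma_dot must be non-negative")
    m0 = mu_zero(phi, coeffs, floor=None)
    mi = mu_inf(phi, coeffs, floor=None)
    x = coeffs.k_time_const * gamma_dot
    shape = (1.0 + np.log1p(x)) / (1.0 + x)
    out = 0.5 * (mi + (m0 - mi) * shape) * (1.0 + phi)
    if floor is not None:
        out = np.maximum(out, floor)
    return out


def plasma_viscous_stress(
    phi, Dp: TensorField2D, props: FluidProperties = FluidProperties()
) -> TensorField2D:
    """Deviatoric (viscous) part of the plasma stress: 2 mu_p (1-phi) D_p."""
    phi = _check_phi(phi)
    c = 2.0 * props.plasma_viscosity * (1.0 - phi)
    return TensorField2D(
        xx=c * Dp.xx, xy=c * Dp.xy, yy=c * Dp.yy,
        tt=None if Dp.tt is None else c * Dp.tt,
    )


def plasma_stress(
    p, phi, Dp: TensorField2D, props: FluidProperties = FluidProperties()
) -> TensorField2D:
    """Plasma-phase Cauchy stress T_p = -p(1-phi) I + 2 mu_p (1-phi) D_p."""
    phi = _check_phi(phi)
    p = np.asarray(p, dtype=float)
    T = plasma_viscous_stress(phi, Dp, props)
    iso = -p * (1.0 - phi)
    T.xx = T.xx + iso
    T.yy = T.yy + iso
    if Dp.tt is not None:
        T.tt = T.tt + iso
    elif np.ndim(iso) > 0:
        # planar: no hoop component carried
        T.tt = None
    return T


def rbc_stress(
    p,
    phi,
    Dr: TensorField2D,
    coeffs: RheologyCoefficients = RheologyCoefficients(),
    *,
    lambda_r: float = 0.0,
    floor: float | None = DEFAULT_VISCOSITY_FLOOR,
) -> TensorField2D:
    """RBC-phase Cauchy stress T_r = [-p phi + lambda_r phi tr(D_r)] I + 2 mu_r phi D_r.

    ``mu_r`` is evaluated from phi and the generalized shear rate of ``Dr``.
    ``lambda_r`` (second viscosity of the RBC phase) defaults to zero.
    """
    phi = _check_phi(phi)
    p = np.asarray(p, dtype=float)
    gdot = generalized_shear_rate(Dr)
    mu_r = rbc_viscosity(phi, gdot, coeffs, floor=floor)
    c = 2.0 * mu_r * phi
    iso = -p * phi + lambda_r * phi * Dr.trace()
    T = TensorField2D(
        xx=c * Dr.xx + iso,
        xy=c * Dr.xy,
        yy=c * Dr.yy + iso,
        tt=None if Dr.tt is None else c * Dr.tt + iso,
    )
    return T
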