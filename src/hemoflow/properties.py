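"""Material properties of the two blood phases.

The blood is modelled as two interpenetrating continua: Newtonian plasma
(the carrier) and a shear-thinning red-blood-cell (RBC) phase.  The default
numbers are for healthy human blood at body temperature: plasma density
1027 kg/m^3 and viscosity 0.96 cP, RBC density 1093 kg/m^3, and an RBC
characteristic size a = 8 um entering the interphase force laws.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FluidProperties:
    """Densities and viscosities of the two pure phases plus the RBC size.

    Attributes
    ----------
    plasma_density : float
        Mass density of pure plasma, kg/m^3.
    plasma_viscosity : float
        Dynamic viscosity of plasma, Pa*s (0.96 cP by default).
    rbc_density : float
        Mass density of the pure RBC phase, kg/m^3.
    rbc_size_a : float
        RBC characteristic size ``a`` used in the drag and lift laws, m.
    """

    plasma_density: float = 1027.0
    plasma_viscosity: float = 0.96e-3
    rbc_density: float = 1093.0
    rbc_size_a: float = 8.0e-6

    def __post_init__(self) -> None:
        for name in ("plasma_density", "plasma_viscosity", "rbc_density", "rbc_size_a"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class RheologyCoefficients:
    """Coefficients of the RBC-phase viscosity law.

    The zero-shear and infinite-shear viscosities are quadratic polynomials
    in the RBC volume fraction phi, fitted to steady viscometry of whole
    blood; their output is in centipoise and is converted to Pa*s by
    ``output_unit_scale``.  ``k_time_const`` is the shear-thinning time
    constant (s) so that k*gamma_dot is dimensionless.

    mu0(phi)  = 537.002 phi^2 + 55.006 phi - 0.129      [cP]
    muinf(phi) = 27.873 phi^2 - 21.218 phi + 14.439     [cP]
    k = 11 s
    """

    mu0_poly: tuple[float, float, float] = (537.002, 55.006, -0.129)
    muinf_poly: tuple[float, float, float] = (27.873, -21.218, 14.439)
    k_time_const: float = 11.0
    output_unit_scale: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.k_time_const <= 0.0:
            raise ValueError("k_time_const must be strictly positive")
        if self.output_unit_scale <= 0.0:
            raise ValueError("output_unit_scale must be strictly positive")


#: Default floor applied to all evaluated viscosities, Pa*s.  The mu0(phi)
#: polynomial is slightly negative for phi below about 0.0023; flooring at a
#: tenth of the plasma viscosity keeps every effective viscosity physical.
#: The fitted law is trusted for phi in roughly [0.05, 0.6].
DEFAULT_VISCOSITY_FLOOR = 0.1 * FluidProperties().plasma_viscosity
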