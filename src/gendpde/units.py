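"""Reduced-unit mapping between a physical reference state and the mesoscale model.

A mesoparticle lumps together ``phi`` physical molecules.  The unit of length
is set by the mesoparticle number density at the reference state,
``L_ref = n0**(-1/3)``, the unit of energy by the isothermal compressibility,
``u_ref = 1/(n0 * kappaT0)``, and the unit of mass by the coarse-graining
level, ``m_ref = phi * Mw / N_A``.  With these choices the reduced reference
density and the reduced particle mass are exactly 1 and the reduced Tait
modulus is ``1/gamma_T``.  Temperatures carry a factor of k_B, so the reduced
temperature ``T* = k_B T / u_ref`` plays the role of the ideal-gas pressure at
unit density; the reduced reference particle pressure therefore splits as
``pi0* = P0* - T0*``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "KB",
    "NA",
    "SubstanceSpec",
    "ReducedModel",
    "reduce_reference_state",
    "map_transport",
    "convert_convention",
    "ARGON",
    "WATER",
]

#: CODATA 2018 exact values.
KB = 1.380649e-23  # J/K
NA = 6.02214076e23  # 1/mol


@dataclass(frozen=True)
class SubstanceSpec:
    """Physical reference state of a real fluid.

    Parameters
    ----------
    name : str
        Label for the substance.
    T0 : float
        Reference temperature [K].
    P0 : float
        Reference pressure [Pa].
    rho_mass0 : float
        Reference mass density [kg/m^3].
    Mw : float
        Molar mass [kg/mol].
    kappaT0 : float
        Isothermal compressibility at the reference state [1/Pa].
    cV_specific : float
        Specific constant-volume heat capacity [J/(kg K)].
    nu : float
        Kinematic viscosity [m^2/s].
    lam : float
        Thermal conductivity [W/(m K)].
    gammaT : float
        Tait exponent [-].
    phi : int
        Coarse-graining level: physical molecules per mesoparticle.
    """

    name: str
    T0: float
    P0: float
    rho_mass0: float
    Mw: float
    kappaT0: float
    cV_specific: float
    nu: float
    lam: float
    gammaT: float
    phi: int = 5

    def __post_init__(self) -> None:
        for field in ("T0", "P0", "rho_mass0", "Mw", "kappaT0",
                      "cV_specific", "nu", "lam"):
            value = getattr(self, field)
            if not value > 0.0:
                raise ValueError(f"{self.name}: {field} must be positive, got {value}")
        if self.gammaT < 1.0:
            raise ValueError(f"gammaT must be >= 1, got {self.gammaT}")
        if self.phi < 1 or self.phi != int(self.phi):
            raise ValueError(f"phi must be a positive integer, got {self.phi}")


@dataclass(frozen=True)
class ReducedModel:
    """Unit scales and dimensionless parameters derived from a :class:`SubstanceSpec`."""

    L_ref: float  # m
    u_ref: float  # J
    m_ref: float  # kg
    t_ref: float  # s
    T0_star: float
    P0_star: float
    pi0_star: float
    n0_star: float
    CV_star: float
    BT_star: float
    m_star: float
    phi: int

    @property
    def theta_ref(self) -> float:
        """Temperature scale [K]: u_ref expressed in kelvin."""
        return self.u_ref / KB


def reduce_reference_state(spec: SubstanceSpec) -> ReducedModel:
    """Derive the dimensionless mesoparticle model from a physical reference state.

    Returns a :class:`ReducedModel` with ``n0_star == 1`` and ``m_star == 1``
    by construction, ``BT_star == 1/gammaT`` and ``pi0_star == P0_star - T0_star``.
    """
    rho0 = spec.rho_mass0 * NA / spec.Mw        # physical number density [1/m^3]
    n0 = rho0 / spec.phi                        # mesoparticle number density
    m_tilde = spec.Mw / NA                      # physical molecule mass [kg]

    L_ref = n0 ** (-1.0 / 3.0)
    u_ref = 1.0 / (n0 * spec.kappaT0)
    m_ref = spec.phi * m_tilde
    t_ref = math.sqrt(m_ref * L_ref**2 / u_ref)

    T0_star = KB * spec.T0 / u_ref
    P0_star = spec.P0 * spec.kappaT0            # P0 * L_ref^3 / u_ref
    CV_star = spec.cV_specific * spec.phi * m_tilde / KB
    return ReducedModel(
        L_ref=L_ref,
        u_ref=u_ref,
        m_ref=m_ref,
        t_ref=t_ref,
        T0_star=T0_star,
        P0_star=P0_star,
        pi0_star=P0_star - T0_star,
        n0_star=1.0,
        CV_star=CV_star,
        BT_star=1.0 / spec.gammaT,
        m_star=1.0,
        phi=spec.phi,
    )


def map_transport(
    spec: SubstanceSpec, model: ReducedModel, R_cut_star: float
) -> tuple[float, float]:
    """Map macroscopic transport coefficients onto mesoscopic (gamma*, kappa*).

    The kinematic viscosity of a DPD fluid has a kinetic contribution
    ``45 T*/(4 pi gamma* R^3)`` and a collisional contribution
    ``2 pi gamma* R^5 n0^2 / 1575``; equating their sum to the reduced
    experimental viscosity gives a quadratic in ``gamma*``.  The *larger* root
    is taken: on that branch gamma* decreases with increasing R_cut, which is
    the physical parametrization (friction spread over more neighbors).  The
    thermal conductivity relation is then linear in ``kappa*``:
    ``lambda* = 45 CV* T*/(2 pi gamma* R^3) + 2 pi kappa* R^5 n0^2/(315 T*^2)``.

    Returns
    -------
    (gamma_star, kappa_star) : tuple of float

    Raises
    ------
    ValueError
        If the viscosity quadratic has no real positive root at this cutoff.
    """
    if R_cut_star <= 0:
        raise ValueError("R_cut_star must be positive")
    T = model.T0_star
    R3 = R_cut_star**3
    R5 = R_cut_star**5

    nu_star = spec.nu * model.t_ref / model.L_ref**2
    lam_star = spec.lam * model.t_ref * model.L_ref / KB  # includes theta_ref/u_ref

    # B*gamma^2 - nu*gamma + A = 0
    A = 45.0 * T / (4.0 * math.pi * R3)
    B = 2.0 * math.pi * R5 / 1575.0
    disc = nu_star**2 - 4.0 * A * B
    if disc < 0.0:
        raise ValueError(
            f"transport parametrization infeasible at R_cut*={R_cut_star}: "
            f"reduced viscosity {nu_star:.4g} below the minimum "
            f"{2.0 * math.sqrt(A * B):.4g} attainable with this cutoff"
        )
    gamma_star = (nu_star + math.sqrt(disc)) / (2.0 * B)

    kinetic = 45.0 * model.CV_star * T / (2.0 * math.pi * gamma_star * R3)
    kappa_star = (lam_star - kinetic) * 315.0 * T**2 / (2.0 * math.pi * R5)
    return gamma_star, kappa_star


def convert_convention(
    value: float,
    dims: tuple[float, float, float],
    model: ReducedModel,
    direction: str = "forward",
) -> float:
    """Convert between this package's reduced units and the k_B T convention.

    A quantity with dimensions ``[y] = L^alpha m^beta u^gamma`` obeys
    ``y** = y* phi^(alpha/3) (T*)^gamma`` where ``y**`` is the value in the
    standard DPD convention (length from the *physical* number density, energy
    k_B T).  ``direction`` is ``"forward"`` (* -> **) or ``"inverse"``.
    """
    alpha, _beta, gamma = dims
    factor = model.phi ** (alpha / 3.0) * model.T0_star**gamma
    if direction == "forward":
        return value * factor
    if direction == "inverse":
        return value / factor
    raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")


#: Liquid argon reference state near the triple-point liquid branch.
ARGON = SubstanceSpec(
    name="argon",
    T0=125.7,
    P0=85.31e6,
    rho_mass0=1419.7,
    Mw=39.948e-3,
    kappaT0=1.49e-9,
    cV_specific=5.20e2,
    nu=1.69e-7,
    lam=0.139,
    gammaT=6.0,
    phi=5,
)

#: Liquid water at near-ambient conditions.
WATER = SubstanceSpec(
    name="water",
    T0=293.16,
    P0=0.10e6,
    rho_mass0=998.20,
    Mw=18.015e-3,
    kappaT0=4.60e-10,
    cV_specific=4.15e3,
    nu=1.00e-6,
    lam=0.598,
    gammaT=5.0,
    phi=5,
)
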