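"""Mesoparticle internal thermodynamics: the modified Tait closure.

Each mesoparticle carries an internal energy ``u`` and a local density ``n``
(all reduced units, k_B = 1).  The internal state is closed by the modified
Tait equation of state for weakly compressible liquids,

    pi(n) = pi0 + B_T [(n/n0)**gammaT - 1],

whose density potential ``Psi(n)`` satisfies ``pi = n**2 dPsi/dn``.  The
temperature part of the free energy, ``Phi(theta)``, is chosen so the entropy
and its temperature derivative vanish as theta -> 0 (Third Law); for the
near-ambient conditions simulated here the high-temperature limit
``u = Psi(n) + C_V theta`` applies and is the default closure.

Dressed intensive variables (theta, pi) live in the energetic representation;
the bare variables (theta~, pi~) of the entropic representation differ by
O(1/C_V) terms.  Under the high-temperature closure the transformation is
closed-form: ``theta~ = theta / (1 - 1/C_V)`` and ``pi~ = pi``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TaitParams",
    "particle_pressure",
    "compressibility",
    "psi",
    "n_min",
    "thermo_potentials",
    "theta_from_energy",
    "bare_from_dressed",
    "tait_params_from_model",
]


@dataclass(frozen=True)
class TaitParams:
    """Reduced parameters of the mesoparticle internal thermodynamics.

    Attributes
    ----------
    pi0 : float
        Reference particle pressure.
    BT : float
        Tait modulus; equals ``1/gammaT`` in reduced units.
    gammaT : float
        Tait exponent (>= 1).
    n0 : float
        Reference density (1 in reduced units).
    CV : float
        Particle heat capacity in units of k_B; must exceed 1 for the
        bare/dressed transform to be defined.
    theta0 : float
        Reference temperature of the Third-Law entropy form.  Only the
        full (low-temperature) closure depends on it.
    """

    pi0: float
    BT: float
    gammaT: float
    n0: float = 1.0
    CV: float = 10.0
    theta0: float = 1e-3

    def __post_init__(self) -> None:
        if self.BT <= 0:
            raise ValueError(f"BT must be positive, got {self.BT}")
        if self.gammaT < 1:
            raise ValueError(f"gammaT must be >= 1, got {self.gammaT}")
        if self.n0 <= 0:
            raise ValueError(f"n0 must be positive, got {self.n0}")
        if self.theta0 <= 0:
            raise ValueError(f"theta0 must be positive, got {self.theta0}")


def tait_params_from_model(model, theta0_fraction: float = 0.1) -> TaitParams:
    """Build :class:`TaitParams` from a :class:`~gendpde.units.ReducedModel`.

    ``theta0`` defaults to ``theta0_fraction * T0_star``, deep below the
    simulated temperatures so the high-temperature closure is accurate.
    """
    gammaT = 1.0 / model.BT_star
    return TaitParams(
        pi0=model.pi0_star,
        BT=model.BT_star,
        gammaT=gammaT,
        n0=model.n0_star,
        CV=model.CV_star,
        theta0=theta0_fraction * model.T0_star,
    )


def _check_density(n) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("density must be strictly positive")
    return n


def particle_pressure(n, p: TaitParams):
    """Tait particle pressure ``pi(n)``; strictly increasing in ``n``."""
    n = _check_density(n)
    return p.pi0 + p.BT * ((n / p.n0) ** p.gammaT - 1.0)


def compressibility(n, p: TaitParams):
    """Isothermal compressibility ``kappa_T(n) = (1/(BT*gammaT)) (n0/n)**gammaT``.

    At ``n = n0`` this equals the reduced physical compressibility
    ``1/(BT*gammaT)`` (= 1 when BT = 1/gammaT), and it vanishes as n -> inf.
    """
    n = _check_density(n)
    return (p.n0 / n) ** p.gammaT / (p.BT * p.gammaT)


def psi(n, p: TaitParams):
    """Density potential ``Psi(n)`` with ``n**2 Psi'(n) = pi(n)``.

    ``Psi(n) = (BT - pi0)/n + BT/((gammaT-1) n0) (n/n0)**(gammaT-1)``.
    Diverges as n -> 0+ when BT > pi0, with a minimum at :func:`n_min`.
    """
    n = _check_density(n)
    return (p.BT - p.pi0) / n + p.BT / ((p.gammaT - 1.0) * p.n0) * (
        (n / p.n0) ** (p.gammaT - 1.0)
    )


def n_min(p: TaitParams) -> float:
    """Density minimizing ``Psi``: ``n0 (1 - pi0/BT)**(1/gammaT)``; pi(n_min) = 0."""
    if p.pi0 >= p.BT:
        raise ValueError(
            f"n_min undefined: pi0={p.pi0} >= BT={p.BT} (Psi has no interior minimum)"
        )
    return p.n0 * (1.0 - p.pi0 / p.BT) ** (1.0 / p.gammaT)


def thermo_potentials(theta, n, p: TaitParams):
    """Free energy, entropy and internal energy of the full Third-Law closure.

    Returns ``(f, s, u)`` with ``f = Psi(n) + Phi(theta)``,
    ``Phi = -(CV/2) theta ln(1 + (theta/theta0)^2)``, ``s = -df/dtheta`` and
    ``u = f + theta s``.  The Legendre identity ``u - f = theta s`` holds by
    construction; as theta -> 0 both s and ds/dtheta vanish.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be strictly positive")
    x2 = (theta / p.theta0) ** 2
    log1 = np.log1p(x2)
    f = psi(n, p) - 0.5 * p.CV * theta * log1
    s = 0.5 * p.CV * (2.0 * x2 / (1.0 + x2) + log1)
    u = psi(n, p) + p.CV * theta * x2 / (1.0 + x2)
    return f, s, u


def theta_from_energy(u, n, p: TaitParams):
    """Invert the high-temperature closure: ``theta = (u - Psi(n))/CV``.

    Raises
    ------
    ValueError
        If ``u <= Psi(n)``, i.e. a particle colder than absolute zero in
        the model — an unphysical state (reduce the time step).
    """
    u = np.asarray(u, dtype=float)
    excess = u - psi(n, p)
    if np.any(excess <= 0):
        raise ValueError(
            "unphysical internal state: u <= Psi(n) for at least one particle "
            "(negative dressed temperature); a smaller time step may be needed"
        )
    return excess / p.CV


def bare_from_dressed(theta, pi, p: TaitParams):
    """Transform dressed (theta, pi) to bare (theta~, pi~).

    Under the high-temperature closure the entropic-representation variables
    are ``theta~ = theta / (1 - 1/CV)`` and ``pi~ = pi`` exactly.  The
    correction is O(1/CV) and vanishes for large mesoparticles.
    """
    if p.CV <= 1.0:
        raise ValueError(f"bare/dressed transform requires CV > 1, got CV={p.CV}")
    theta = np.asarray(theta, dtype=float)
    pi = np.asarray(pi, dtype=float)
    theta_bare = theta / (1.0 - 1.0 / p.CV)
    return theta_bare, pi
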