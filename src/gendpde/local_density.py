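"""Kernels and local-density estimators.

Two estimators assign each particle a density from its neighborhood:

* **LDE-A** — the traditional DPD kernel sum ``n_i^b = sum_j w(r_ij)`` with
  the normalized quadratic kernel.  In structured liquids the correlation
  hole around each particle makes this underestimate the density, which
  drives a pairing/clustering instability of density-dependent potentials.
* **LDE-B** — a corrected particle volume obtained by integrating the
  approximate partition-of-unity function ``w~/(w~ + n^b)`` over space with a
  rescaled cutoff ``R~ = R_cut / f_cut``.  The integral has a closed form in
  both 2-D and 3-D; the density is ``n = 1/V``.

The force on a particle needs the sensitivity ``zeta = dn/dn^b`` of the
corrected density to the raw kernel sum; for LDE-A ``zeta == 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelConfig",
    "DensityFields",
    "kernel_w",
    "kernel_w_prime",
    "kernel_fourier",
    "lde_a",
    "volume_lde_b",
    "volume_lde_b_quadrature",
    "dV_dk",
    "zeta",
    "density_fields",
]


@dataclass(frozen=True)
class KernelConfig:
    """Kernel geometry: cutoff, volume-correction rescaling, dimensionality."""

    R_cut: float
    f_cut: float = 1.0
    dim: int = 3

    def __post_init__(self) -> None:
        if self.R_cut <= 0:
            raise ValueError(f"R_cut must be positive, got {self.R_cut}")
        if self.f_cut < 1.0:
            raise ValueError(f"f_cut must be >= 1, got {self.f_cut}")
        if self.dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.dim}")

    @property
    def R_tilde(self) -> float:
        """Rescaled cutoff used only in the volume closed form."""
        return self.R_cut / self.f_cut

    @property
    def k_prefactor(self) -> float:
        """Factor mapping n^b to the dimensionless k of the volume formula."""
        if self.dim == 3:
            return (2.0 * math.pi / 15.0) * self.R_tilde**3
        return (math.pi / 6.0) * self.R_tilde**2


@dataclass
class DensityFields:
    """Per-particle density quantities for one configuration."""

    n_b: np.ndarray          # raw kernel-sum density
    k: np.ndarray            # dimensionless volume-formula argument
    V: np.ndarray            # particle volume
    n: np.ndarray            # thermodynamic density used by the EoS
    zeta: np.ndarray         # dn/dn_b
    estimator: str = field(default="lde_b")


def kernel_w(r, cfg: KernelConfig):
    """Normalized quadratic kernel ``w(r)``.

    3-D: ``15/(2 pi R^3) (1 - r/R)^2`` for r < R, else 0 (2-D analog
    ``6/(pi R^2) (1 - r/R)^2``); continuous at the cutoff and normalized to
    unit integral over all space.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    R = cfg.R_cut
    if cfg.dim == 3:
        amp = 15.0 / (2.0 * math.pi * R**3)
    else:
        amp = 6.0 / (math.pi * R**2)
    return np.where(r < R, amp * (1.0 - r / R) ** 2, 0.0)


def kernel_w_prime(r, cfg: KernelConfig):
    """Radial derivative ``dw/dr`` of the quadratic kernel (non-positive)."""
    r = np.asarray(r, dtype=float)
    R = cfg.R_cut
    if cfg.dim == 3:
        amp = 15.0 / (2.0 * math.pi * R**3)
    else:
        amp = 6.0 / (math.pi * R**2)
    return np.where(r < R, -2.0 * amp / R * (1.0 - r / R), 0.0)


def kernel_fourier(kwave, R_cut: float):
    """Fourier transform of the 3-D quadratic kernel.

    ``w(k) = 30 (4 x - 6 sin x + 2 x cos x) / x^5`` with ``x = k R_cut``;
    tends to 1 as k -> 0 (normalization) and is positive for all k > 0 — the
    property associated with kernels free of the pairwise pairing instability.
    Small arguments are evaluated by series to avoid catastrophic cancellation.
    """
    x = np.atleast_1d(np.asarray(kwave, dtype=float)) * R_cut
    out = np.empty_like(x)
    small = np.abs(x) < 1e-2
    xs = x[small]
    # 30*(4x - 6 sin x + 2x cos x)/x^5 = 1 - x^2/14 + x^4/504 - ...
    out[small] = 1.0 - xs**2 / 14.0 + xs**4 / 504.0
    xl = x[~small]
    out[~small] = 30.0 * (4.0 * xl - 6.0 * np.sin(xl) + 2.0 * xl * np.cos(xl)) / xl**5
    if np.isscalar(kwave) or np.ndim(kwave) == 0:
        return float(out[0])
    return out


def _min_image(delta: np.ndarray, box: float) -> np.ndarray:
    return delta - box * np.round(delta / box)


def lde_a(positions: np.ndarray, box: float, cfg: KernelConfig) -> np.ndarray:
    """Raw kernel-sum density ``n_i^b`` by direct double loop (minimum image).

    Reference implementation for small systems and validation; the dynamics
    engine accumulates the same sums from its neighbor lists.  Requires a
    periodic box edge larger than twice the cutoff.
    """
    positions = np.asarray(positions, dtype=float)
    if box <= 2.0 * cfg.R_cut:
        raise ValueError(
            f"box edge {box} too small for cutoff {cfg.R_cut} (need box > 2 R_cut)"
        )
    N = positions.shape[0]
    n_b = np.zeros(N)
    for i in range(N):
        delta = _min_image(positions[i] - positions, box)
        r = np.sqrt((delta**2).sum(axis=1))
        r[i] = np.inf  # exclude self
        n_b[i] = kernel_w(r, cfg).sum()
    return n_b


def _vol_prefactor(cfg: KernelConfig) -> float:
    if cfg.dim == 3:
        return 4.0 * math.pi / 3.0 * cfg.R_tilde**3
    return math.pi * cfg.R_tilde**2


def volume_lde_b(n_b, cfg: KernelConfig):
    """Closed-form corrected particle volume as a function of ``n_i^b``.

    3-D::

        V = (4 pi/3) R~^3
            - 4 pi R~^3 [ sqrt(k)(1-k) arctan(1/sqrt(k)) + k(1 - ln((1+k)/k)) ]

    with ``k = (2 pi/15) R~^3 n^b``; the 2-D analog uses
    ``k = (pi/6) R~^2 n^b``.  Limits: ``V(n^b=0)`` is the bare kernel volume
    and ``V n^b -> 1`` as ``n^b -> inf``.  Strictly decreasing in ``n^b``.
    """
    n_b = np.asarray(n_b, dtype=float)
    if np.any(n_b < 0):
        raise ValueError("n_b must be non-negative")
    k = cfg.k_prefactor * n_b
    scalar = k.ndim == 0
    k = np.atleast_1d(k)
    V = np.empty_like(k)

    # Direct closed form loses ~eps*k digits to cancellation; switch to the
    # alternating asymptotic series in 1/k well before that matters.
    large = k > 50.0
    ks = k[~large]
    sk = np.sqrt(ks)
    atn = np.arctan2(1.0, sk)              # arctan(1/sqrt(k)), well-defined at k=0
    logterm = np.where(ks > 0, np.log1p(1.0 / np.maximum(ks, 1e-300)), 0.0)
    if cfg.dim == 3:
        corr = 4.0 * math.pi * cfg.R_tilde**3 * (
            sk * (1.0 - ks) * atn + ks * (1.0 - logterm)
        )
    else:
        corr = 2.0 * math.pi * cfg.R_tilde**2 * (sk * atn - 0.5 * ks * logterm)
    V[~large] = _vol_prefactor(cfg) - corr

    kl = k[large]
    if kl.size:
        acc = np.zeros_like(kl)
        invk = 1.0 / kl
        power = invk.copy()
        for m in range(1, 16):
            if cfg.dim == 3:
                coeff = 1.0 / ((m + 1) * (2 * m + 1) * (2 * m + 3))
            else:
                coeff = 1.0 / ((2 * m + 1) * (2 * m + 2))
            acc += (-1.0) ** (m + 1) * coeff * power
            power *= invk
        if cfg.dim == 3:
            V[large] = 4.0 * math.pi * cfg.R_tilde**3 * acc
        else:
            V[large] = 2.0 * math.pi * cfg.R_tilde**2 * acc
    return V[0] if scalar else V


def volume_lde_b_quadrature(n_b: float, cfg: KernelConfig) -> float:
    """Particle volume by adaptive quadrature of the partition-of-unity integral.

    Independent numerical evaluation of the integral behind
    :func:`volume_lde_b`; used as the arbiter of the closed form.
    """
    from scipy.integrate import quad

    k = cfg.k_prefactor * float(n_b)
    if cfg.dim == 3:
        def integrand(x: float) -> float:
            return x**2 * (1.0 - x) ** 2 / ((1.0 - x) ** 2 + k)

        val, _ = quad(integrand, 0.0, 1.0, epsabs=0.0, epsrel=1e-13, limit=200)
        return 4.0 * math.pi * cfg.R_tilde**3 * val

    def integrand2(x: float) -> float:
        return x * (1.0 - x) ** 2 / ((1.0 - x) ** 2 + k)

    val, _ = quad(integrand2, 0.0, 1.0, epsabs=0.0, epsrel=1e-13, limit=200)
    return 2.0 * math.pi * cfg.R_tilde**2 * val


def dV_dk(k, cfg: KernelConfig):
    """Analytic derivative of the closed-form volume with respect to ``k``.

    3-D: ``-4 pi R~^3 [ 3/2 + (1-3k)/(2 sqrt(k)) arctan(1/sqrt(k))
    - ln((1+k)/k) ]``; 2-D: ``-pi R~^2 [ arctan(1/sqrt(k))/sqrt(k)
    - ln((1+k)/k) ]``.  Diverges as k -> 0+ (isolated-particle limit).
    """
    k = np.asarray(k, dtype=float)
    if np.any(k <= 0):
        raise ValueError("dV/dk requires k > 0")
    scalar = k.ndim == 0
    k = np.atleast_1d(k)
    out = np.empty_like(k)

    large = k > 50.0
    ks = k[~large]
    if ks.size:
        sk = np.sqrt(ks)
        atn = np.arctan(1.0 / sk)
        logterm = np.log1p(1.0 / ks)
        if cfg.dim == 3:
            out[~large] = -4.0 * math.pi * cfg.R_tilde**3 * (
                1.5 + (1.0 - 3.0 * ks) / (2.0 * sk) * atn - logterm
            )
        else:
            out[~large] = -math.pi * cfg.R_tilde**2 * (atn / sk - logterm)

    kl = k[large]
    if kl.size:
        # term-by-term derivative of the asymptotic volume series
        acc = np.zeros_like(kl)
        invk = 1.0 / kl
        power = invk * invk
        for m in range(1, 16):
            if cfg.dim == 3:
                coeff = m / ((m + 1) * (2 * m + 1) * (2 * m + 3))
            else:
                coeff = m / ((2 * m + 1) * (2 * m + 2))
            acc += (-1.0) ** m * coeff * power
            power *= invk
        if cfg.dim == 3:
            out[large] = 4.0 * math.pi * cfg.R_tilde**3 * acc
        else:
            out[large] = 2.0 * math.pi * cfg.R_tilde**2 * acc
    return out[0] if scalar else out


def zeta(n_b, cfg: KernelConfig, estimator: str = "lde_b"):
    """Density sensitivity ``zeta = dn/dn^b`` entering the conservative force.

    For LDE-A the thermodynamic density *is* ``n^b`` so ``zeta == 1``.  For
    LDE-B, ``n = 1/V(k(n^b))`` gives
    ``zeta = -(1/V^2) (dV/dk) (dk/dn^b) > 0``.
    """
    n_b = np.asarray(n_b, dtype=float)
    if estimator == "lde_a":
        return np.ones_like(n_b)
    V = volume_lde_b(n_b, cfg)
    k = cfg.k_prefactor * n_b
    return -(1.0 / V**2) * dV_dk(k, cfg) * cfg.k_prefactor


def density_fields(n_b: np.ndarray, cfg: KernelConfig, estimator: str) -> DensityFields:
    """Assemble all per-particle density quantities for one configuration."""
    n_b = np.asarray(n_b, dtype=float)
    if estimator == "lde_a":
        n = n_b.copy()
        with np.errstate(divide="ignore"):
            V = np.where(n_b > 0, 1.0 / np.where(n_b > 0, n_b, 1.0), np.inf)
        return DensityFields(
            n_b=n_b, k=np.zeros_like(n_b), V=V, n=n,
            zeta=np.ones_like(n_b), estimator="lde_a",
        )
    if estimator != "lde_b":
        raise ValueError(f"unknown estimator {estimator!r}")
    k = cfg.k_prefactor * n_b
    V = volume_lde_b(n_b, cfg)
    n = 1.0 / V
    return DensityFields(n_b=n_b, k=k, V=V, n=n, zeta=zeta(n_b, cfg), estimator="lde_b")
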