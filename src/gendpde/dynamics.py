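"""GenDPDE equations of motion and time integration.

Each mesoparticle carries position, momentum and an internal energy ``u_i``.
Pairwise interactions comprise a conservative force derived from the
density-dependent potential, a DPD friction force, a random impulse tied to
the friction by fluctuation-dissipation, an interparticle heat flux driven by
differences of inverse *bare* temperature, and its conjugate random energy
exchange.  The internal-energy balance mirrors every momentum-channel term so
that total energy is conserved up to integration error; the residual drift is
measured every step and removed uniformly from the internal energies.

All pair interactions are antisymmetric (momentum) or pairwise-compensating
(energy), so total momentum is conserved to round-off by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.spatial import cKDTree

from . import eos, local_density as ld
from .eos import TaitParams
from .local_density import DensityFields, KernelConfig

__all__ = [
    "ParticleSystem",
    "SimConfig",
    "StepReport",
    "neighbor_pairs",
    "PairData",
    "conservative_forces",
    "dissipative_and_random_momentum",
    "heat_exchange",
    "step",
    "init_lattice_system",
    "run_simulation",
    "tune_f_cut",
    "RunResult",
]


@dataclass
class ParticleSystem:
    """State of the mesoparticle system in reduced units (m_i = 1)."""

    positions: np.ndarray       # (N, 3), wrapped into [0, box)
    momenta: np.ndarray         # (N, 3)
    u: np.ndarray               # (N,) internal energies
    box: float
    mass: float = 1.0
    # derived per-particle fields, refreshed at the start of every step
    fields: DensityFields | None = None
    theta: np.ndarray | None = None
    pi: np.ndarray | None = None
    theta_bare: np.ndarray | None = None

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return self.box**3

    def kinetic_energy(self) -> float:
        return float(0.5 * (self.momenta**2).sum() / self.mass)

    def total_energy(self) -> float:
        return self.kinetic_energy() + float(self.u.sum())

    def kinetic_temperature(self) -> float:
        """Equipartition temperature with the center-of-mass drift removed.

        Momentum conservation freezes 3 degrees of freedom, hence 3(N-1).
        """
        v = self.momenta / self.mass
        v = v - v.mean(axis=0)
        return float(self.mass * (v**2).sum() / (3.0 * (self.N - 1)))


@dataclass(frozen=True)
class SimConfig:
    """Integration and interaction controls (single R_cut for all channels)."""

    dt: float
    n_equil: int
    n_production: int
    gamma_star: float
    kappa_star: float
    target_T: float
    seed: int = 0
    estimator: str = "lde_b"
    sample_every: int = 10
    rdf_every: int = 100

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_equil < 0 or self.n_production < 0:
            raise ValueError("step counts must be non-negative")
        if self.estimator not in ("lde_a", "lde_b"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class StepReport:
    """Per-step conservation audit and instantaneous observables."""

    drift: float                 # pre-correction total-energy residual
    virial_pair_sum: float       # sum over pairs of r_ij . f^C_ij
    T_kin: float                 # kinetic temperature at the start of the step
    theta_mean: float
    inv_theta_bare_mean: float
    n_mean: float
    E_total: float               # total energy at the start of the step
    sum_p2_over_m: float         # kinetic virial term at the start of the step
    n_pairs: int


@dataclass
class PairData:
    """Neighbor pairs with minimum-image separations inside the cutoff."""

    i: np.ndarray        # (M,)
    j: np.ndarray        # (M,)  i < j
    r: np.ndarray        # (M,) distances
    e: np.ndarray        # (M, 3) unit vectors (r_i - r_j)/r


def neighbor_pairs(positions: np.ndarray, box: float, R_cut: float) -> PairData:
    """All unique pairs with minimum-image distance below ``R_cut``.

    Uses a periodic k-d tree; pairs are returned sorted by (i, j) so that
    downstream random-number consumption is independent of traversal order.
    Requires ``box > 2 R_cut`` for minimum-image validity.
    """
    if box <= 2.0 * R_cut:
        raise ValueError(f"box edge {box} too small for cutoff {R_cut}")
    pos = np.mod(positions, box)
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(R_cut, output_type="ndarray")
    if pairs.size == 0:
        return PairData(
            i=np.empty(0, dtype=np.intp),
            j=np.empty(0, dtype=np.intp),
            r=np.empty(0),
            e=np.empty((0, 3)),
        )
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    i, j = pairs[:, 0], pairs[:, 1]
    delta = pos[i] - pos[j]
    delta -= box * np.round(delta / box)
    r = np.sqrt((delta**2).sum(axis=1))
    keep = r < R_cut
    i, j, r, delta = i[keep], j[keep], r[keep], delta[keep]
    if np.any(r == 0.0):
        raise ValueError(
            "overlapping particles (r_ij = 0): force direction undefined; "
            "re-initialize with jitter"
        )
    e = delta / r[:, None]
    return PairData(i=i, j=j, r=r, e=e)


class NeighborList:
    """Verlet neighbor list: k-d tree pairs within ``R_cut + skin``.

    The candidate list is rebuilt only when some particle has moved more than
    half the skin since the last build; between rebuilds only the pair
    separations are recomputed, which preserves exactness (no pair inside
    ``R_cut`` can be missed while the displacement bound holds).
    """

    def __init__(self, box: float, R_cut: float, skin: float = 0.3):
        if box <= 2.0 * (R_cut + skin):
            skin = max(0.0, box / 2.0 - R_cut - 1e-9)
        self.box = box
        self.R_cut = R_cut
        self.skin = skin
        self._pairs: np.ndarray | None = None
        self._ref: np.ndarray | None = None

    def _rebuild(self, positions: np.ndarray) -> None:
        pos = np.mod(positions, self.box)
        tree = cKDTree(pos, boxsize=self.box)
        pairs = tree.query_pairs(self.R_cut + self.skin, output_type="ndarray")
        if pairs.size:
            pairs = np.sort(pairs, axis=1)
            pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
        self._pairs = pairs.reshape(-1, 2)
        self._ref = pos

    def pairs(self, positions: np.ndarray) -> PairData:
        pos = np.mod(positions, self.box)
        if self._pairs is None:
            self._rebuild(pos)
        else:
            disp = pos - self._ref
            disp -= self.box * np.rint(disp * (1.0 / self.box))
            if self.skin <= 0.0 or np.einsum("ij,ij->i", disp, disp).max() > (
                0.5 * self.skin
            ) ** 2:
                self._rebuild(pos)
        cand = self._pairs
        if cand.size == 0:
            return PairData(
                i=np.empty(0, dtype=np.intp), j=np.empty(0, dtype=np.intp),
                r=np.empty(0), e=np.empty((0, 3)),
            )
        delta = pos[cand[:, 0]] - pos[cand[:, 1]]
        delta -= self.box * np.rint(delta * (1.0 / self.box))
        r2 = np.einsum("ij,ij->i", delta, delta)
        keep = r2 < self.R_cut**2
        i, j, delta = cand[keep, 0], cand[keep, 1], delta[keep]
        r = np.sqrt(r2[keep])
        if r.size and r.min() == 0.0:
            raise ValueError(
                "overlapping particles (r_ij = 0): force direction undefined"
            )
        e = delta / r[:, None]
        return PairData(i=i, j=j, r=r, e=e)


def _accumulate(values, idx_i, idx_j, N, sign_j=-1.0):
    """Per-particle sums of a per-pair quantity (vector or scalar)."""
    if values.ndim == 1:
        return (
            np.bincount(idx_i, weights=values, minlength=N)
            + sign_j * np.bincount(idx_j, weights=values, minlength=N)
        )
    out = np.empty((N, values.shape[1]))
    for d in range(values.shape[1]):
        out[:, d] = np.bincount(
            idx_i, weights=values[:, d], minlength=N
        ) + sign_j * np.bincount(idx_j, weights=values[:, d], minlength=N)
    return out


def refresh_fields(
    system: ParticleSystem,
    pairs: PairData,
    kernel: KernelConfig,
    tait: TaitParams,
    estimator: str,
) -> None:
    """Recompute densities and intensive variables for the current positions."""
    w = ld.kernel_w(pairs.r, kernel)
    n_b = np.bincount(pairs.i, weights=w, minlength=system.N) + np.bincount(
        pairs.j, weights=w, minlength=system.N
    )
    system.fields = ld.density_fields(n_b, kernel, estimator)
    system.theta = eos.theta_from_energy(system.u, system.fields.n, tait)
    system.pi = eos.particle_pressure(system.fields.n, tait)
    system.theta_bare, _ = eos.bare_from_dressed(system.theta, system.pi, tait)


def conservative_forces(
    system: ParticleSystem, pairs: PairData, kernel: KernelConfig
) -> tuple[np.ndarray, float, np.ndarray]:
    """Pairwise conservative forces from the density-dependent potential.

    Returns ``(f_pair, virial_sum, F_per_particle)`` where
    ``f_pair[m] = -(pi_i zeta_i / n_i^2 + pi_j zeta_j / n_j^2) w'(r) e`` is the
    force on particle i of pair m (the force on j is its negative) and
    ``virial_sum = sum_m r_m . f_pair[m]``.
    """
    fld = system.fields
    coef = system.pi * fld.zeta / fld.n**2
    wprime = ld.kernel_w_prime(pairs.r, kernel)
    cmag = -(coef[pairs.i] + coef[pairs.j]) * wprime   # >= 0 for repulsion
    f_pair = cmag[:, None] * pairs.e
    virial_sum = float((cmag * pairs.r).sum())
    F = _accumulate(f_pair, pairs.i, pairs.j, system.N)
    return f_pair, virial_sum, F


def _omega_p(r: np.ndarray, R_cut: float) -> np.ndarray:
    """Non-normalized quadratic weight for the dissipative channels."""
    return (1.0 - r / R_cut) ** 2


def dissipative_and_random_momentum(
    system: ParticleSystem,
    pairs: PairData,
    kernel: KernelConfig,
    cfg: SimConfig,
    rng: np.random.Generator,
    vij: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Friction forces and fluctuation-dissipation random impulses.

    Returns per-pair ``(f_D, dp_R)``: the friction force
    ``-gamma_ij (v_ij . e) e`` and the random impulse
    ``sqrt((theta_i + theta_j) gamma_ij) Omega e sqrt(dt)`` with one fresh
    standard Gaussian ``Omega`` per pair per step, symmetric under i<->j so
    each pair impulse is equal and opposite on the two particles.
    """
    gamma_ij = cfg.gamma_star * _omega_p(pairs.r, kernel.R_cut)
    if vij is None:
        v = system.momenta / system.mass
        vij = v[pairs.i] - v[pairs.j]
    vdote = np.einsum("ij,ij->i", vij, pairs.e)
    f_D = -(gamma_ij * vdote)[:, None] * pairs.e
    omega = rng.standard_normal(pairs.r.shape[0])
    amp = np.sqrt((system.theta[pairs.i] + system.theta[pairs.j]) * gamma_ij)
    dp_R = (amp * omega * math.sqrt(cfg.dt))[:, None] * pairs.e
    return f_D, dp_R


def heat_exchange(
    system: ParticleSystem,
    pairs: PairData,
    kernel: KernelConfig,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Interparticle conduction and its random counterpart.

    Returns per-pair ``(qdot, du_R)``: the deterministic heat flux
    ``-kappa_ij (1/theta~_j - 1/theta~_i)`` (energy flows from hot to cold)
    and the antisymmetric random exchange with variance ``2 kappa_ij dt``.
    Both are added to particle i and subtracted from particle j, so pair
    energy exchange sums to zero identically.
    """
    kappa_ij = cfg.kappa_star * _omega_p(pairs.r, kernel.R_cut)
    inv_tb = 1.0 / system.theta_bare
    qdot = -kappa_ij * (inv_tb[pairs.j] - inv_tb[pairs.i])
    omega = rng.standard_normal(pairs.r.shape[0])
    du_R = np.sqrt(2.0 * kappa_ij) * omega * math.sqrt(cfg.dt)
    return qdot, du_R


def step(
    system: ParticleSystem,
    tait: TaitParams,
    kernel: KernelConfig,
    cfg: SimConfig,
    rng: np.random.Generator,
    nlist: NeighborList | None = None,
) -> StepReport:
    """Advance the system one time step in place.

    Sequence: neighbor refresh -> densities and intensive variables ->
    pair forces, noises and heat terms (one Gaussian draw per pair per
    channel) -> velocity-Verlet update of positions/momenta with the
    start-of-step pair terms -> explicit Euler update of the internal
    energies with the same terms (including the random-work double sum) ->
    removal of the residual total-energy drift, uniformly across particles.
    """
    dt = cfg.dt
    N = system.N
    if nlist is not None:
        pairs = nlist.pairs(system.positions)
    else:
        pairs = neighbor_pairs(system.positions, system.box, kernel.R_cut)
    refresh_fields(system, pairs, kernel, tait, cfg.estimator)

    E0 = system.total_energy()
    T_kin = system.kinetic_temperature()
    sum_p2 = float((system.momenta**2).sum() / system.mass)

    v = system.momenta / system.mass
    vij = v[pairs.i] - v[pairs.j]

    f_pair, virial_sum, F_C = conservative_forces(system, pairs, kernel)
    f_D, dp_R = dissipative_and_random_momentum(
        system, pairs, kernel, cfg, rng, vij=vij
    )
    qdot, du_R = heat_exchange(system, pairs, kernel, cfg, rng)

    F_D = _accumulate(f_D, pairs.i, pairs.j, N)
    S = _accumulate(dp_R, pairs.i, pairs.j, N)   # summed random impulses

    # internal-energy balance: each pair's work terms accrue equally to i and j
    pair_work = -0.5 * dt * np.einsum("ij,ij->i", vij, f_pair + f_D) - 0.5 * np.einsum(
        "ij,ij->i", vij, dp_R
    )
    du = _accumulate(pair_work, pairs.i, pairs.j, N, sign_j=+1.0)
    du += _accumulate(qdot * dt + du_R, pairs.i, pairs.j, N, sign_j=-1.0)
    du -= np.einsum("ij,ij->i", S, S) / (2.0 * system.mass)

    dp = (F_C + F_D) * dt + S
    # velocity-Verlet with frozen (start-of-step) forces: the half-step
    # momentum moves the positions, then the second half-kick completes dp.
    system.positions = np.mod(
        system.positions + (system.momenta + 0.5 * dp) / system.mass * dt,
        system.box,
    )
    system.momenta = system.momenta + dp
    system.u = system.u + du

    E1 = system.total_energy()
    drift = E1 - E0
    system.u -= drift / N

    psi_floor = eos.psi(system.fields.n, tait)
    if np.any(system.u <= psi_floor):
        bad = int(np.argmin(system.u - psi_floor))
        raise RuntimeError(
            f"step failed: particle {bad} reached u <= Psi(n) "
            f"(u={system.u[bad]:.4g}, Psi={psi_floor[bad]:.4g}); "
            "a smaller time step is likely required"
        )

    return StepReport(
        drift=float(drift),
        virial_pair_sum=virial_sum,
        T_kin=T_kin,
        theta_mean=float(system.theta.mean()),
        inv_theta_bare_mean=float((1.0 / system.theta_bare).mean()),
        n_mean=float(system.fields.n.mean()),
        E_total=E0,
        sum_p2_over_m=sum_p2,
        n_pairs=pairs.r.shape[0],
    )


def init_lattice_system(
    N: int,
    tait: TaitParams,
    target_T: float,
    rng: np.random.Generator,
    jitter: float = 0.05,
    n0: float = 1.0,
) -> ParticleSystem:
    """Simple-cubic start at density ``n0`` with jitter and Maxwell momenta.

    ``N`` is rounded to the nearest perfect cube.  Internal energies start at
    ``Psi(n0) + C_V T``, i.e. every particle at the target temperature.
    """
    M = max(2, round(N ** (1.0 / 3.0)))
    N = M**3
    spacing = n0 ** (-1.0 / 3.0)
    box = M * spacing
    grid = np.arange(M) * spacing
    pos = np.stack(np.meshgrid(grid, grid, grid, indexing="ij"), axis=-1).reshape(-1, 3)
    pos = pos + rng.uniform(-jitter * spacing, jitter * spacing, size=pos.shape)
    mom = rng.standard_normal((N, 3)) * math.sqrt(target_T)
    mom -= mom.mean(axis=0)
    u = np.full(N, float(eos.psi(n0, tait)) + tait.CV * target_T)
    return ParticleSystem(positions=np.mod(pos, box), momenta=mom, u=u, box=box)


@dataclass
class RunResult:
    """Output of :func:`run_simulation`."""

    series: "pandas.DataFrame"          # per-sample thermodynamic time series
    system: ParticleSystem              # final state
    rdf_frames: list = dataclass_field(default_factory=list)  # sampled positions
    frame_fields: list = dataclass_field(default_factory=list)  # per-frame u, n, theta
    config: SimConfig | None = None


def run_simulation(
    tait: TaitParams,
    kernel: KernelConfig,
    cfg: SimConfig,
    N: int = 1000,
    system: ParticleSystem | None = None,
    collect_frames: bool = True,
) -> RunResult:
    """Equilibrate by velocity rescaling, then run microcanonical production.

    During the ``n_equil`` equilibration steps the momenta are rescaled every
    step toward ``target_T``; production is strictly energy conserving (post
    drift correction).  Observables are recorded every ``sample_every``
    production steps; position snapshots for the radial distribution function
    every ``rdf_every`` steps.  Fully reproducible from (config, seed).
    """
    import pandas as pd

    rng = np.random.Generator(np.random.Philox(cfg.seed))
    if system is None:
        system = init_lattice_system(N, tait, cfg.target_T, rng)
    nlist = NeighborList(system.box, kernel.R_cut)

    for _ in range(cfg.n_equil):
        step(system, tait, kernel, cfg, rng, nlist=nlist)
        T_now = system.kinetic_temperature()
        system.momenta *= math.sqrt(cfg.target_T / T_now)

    records = []
    frames = []
    frame_fields = []
    for istep in range(cfg.n_production):
        report = step(system, tait, kernel, cfg, rng, nlist=nlist)
        if istep % cfg.sample_every == 0:
            records.append(
                {
                    "step": istep,
                    "time": istep * cfg.dt,
                    "T_kin": report.T_kin,
                    "theta_mean": report.theta_mean,
                    "inv_theta_bare_mean": report.inv_theta_bare_mean,
                    "n_mean": report.n_mean,
                    "P": (report.sum_p2_over_m + report.virial_pair_sum)
                    / (3.0 * system.volume),
                    "E_total": report.E_total,
                    "drift": report.drift,
                }
            )
        if collect_frames and istep % cfg.rdf_every == 0:
            frames.append(system.positions.copy())
            frame_fields.append(
                {
                    "u": system.u.copy(),
                    "n": system.fields.n.copy(),
                    "theta": system.theta.copy(),
                }
            )

    series = pd.DataFrame.from_records(records)
    return RunResult(
        series=series,
        system=system,
        rdf_frames=frames,
        frame_fields=frame_fields,
        config=cfg,
    )


def tune_f_cut(
    tait: TaitParams,
    R_cut: float,
    cfg: SimConfig,
    N: int = 216,
    n_pilot: tuple[int, int] = (1000, 1000),
    bounds: tuple[float, float] = (1.0, 2.0),
    tol: float = 5e-3,
    max_iter: int = 8,
) -> float:
    """Bisect the volume-correction factor so a pilot run sits at n0.

    The corrected mean density decreases monotonically with ``f_cut`` (a
    smaller effective kernel volume raises the density estimate); short
    pilot runs (``n_pilot`` equilibration/production steps) bracket the
    factor at which the production-mean density matches the reference
    density, reconstructing how tabulated per-state-point factors are
    obtained.  Coarse by construction: pilot noise limits ``tol``.
    """

    def mean_density(f_cut: float) -> float:
        kernel = KernelConfig(R_cut=R_cut, f_cut=f_cut, dim=3)
        pilot_cfg = SimConfig(
            dt=cfg.dt, n_equil=n_pilot[0], n_production=n_pilot[1],
            gamma_star=cfg.gamma_star, kappa_star=cfg.kappa_star,
            target_T=cfg.target_T, seed=cfg.seed, estimator="lde_b",
            sample_every=cfg.sample_every,
        )
        result = run_simulation(tait, kernel, pilot_cfg, N=N, collect_frames=False)
        return float(result.series["n_mean"].mean())

    lo, hi = bounds
    n_lo, n_hi = mean_density(lo), mean_density(hi)
    if not (n_lo - tait.n0) * (n_hi - tait.n0) < 0:
        raise ValueError(
            f"f_cut bounds {bounds} do not bracket n0={tait.n0} "
            f"(pilot densities {n_lo:.3f}, {n_hi:.3f})"
        )
    increasing = n_hi > n_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        n_mid = mean_density(mid)
        if abs(n_mid - tait.n0) < tol:
            return mid
        if (n_mid < tait.n0) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
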