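"""Equations of motion: forces, noises, heat exchange, integrator."""

import math

import numpy as np
import pytest

from gendpde.dynamics import (
    NeighborList,
    SimConfig,
    StepReport,
    conservative_forces,
    dissipative_and_random_momentum,
    heat_exchange,
    init_lattice_system,
    neighbor_pairs,
    refresh_fields,
    run_simulation,
    step,
)
from gendpde.eos import psi, theta_from_energy
from gendpde.local_density import KernelConfig


def make_system(positions, box, tait, theta, rng, momenta=None):
    """Assemble a ParticleSystem with all particles at dressed temperature theta."""
    from gendpde.dynamics import ParticleSystem

    positions = np.asarray(positions, dtype=float)
    N = positions.shape[0]
    if momenta is None:
        momenta = np.zeros((N, 3))
    system = ParticleSystem(
        positions=np.mod(positions, box),
        momenta=np.asarray(momenta, dtype=float),
        u=np.zeros(N),
        box=box,
    )
    return system


def equilibrated_u(system, pairs, kernel, tait, estimator, theta):
    """Set internal energies so every particle sits at dressed temperature theta."""
    from gendpde.local_density import density_fields, kernel_w

    w = kernel_w(pairs.r, kernel)
    n_b = np.bincount(pairs.i, weights=w, minlength=system.N) + np.bincount(
        pairs.j, weights=w, minlength=system.N
    )
    fields = density_fields(n_b, kernel, estimator)
    system.u = np.asarray(psi(fields.n, tait)) + tait.CV * np.asarray(theta)
    refresh_fields(system, pairs, kernel, tait, estimator)


def clustered_positions(rng, n, center=4.0, side=1.2):
    """n points inside a cube of the given side: all pairs within the cutoff."""
    return center + rng.uniform(-0.5 * side, 0.5 * side, size=(n, 3))


class TestNeighborPairs:
    def test_far_pair_empty(self):
        pos = np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 5.0]])
        pd = neighbor_pairs(pos, 10.0, 2.0)
        assert pd.r.size == 0

    def test_matches_brute_force(self, rng):
        box, R_cut, N = 8.0, 2.1564, 100
        pos = rng.uniform(0, box, size=(N, 3))
        pd = neighbor_pairs(pos, box, R_cut)
        found = {(int(a), int(b)) for a, b in zip(pd.i, pd.j)}
        expected = set()
        for i in range(N):
            for j in range(i + 1, N):
                d = pos[i] - pos[j]
                d -= box * np.round(d / box)
                if (d**2).sum() < R_cut**2:
                    expected.add((i, j))
        assert found == expected

    def test_each_pair_once_and_ordered(self, rng):
        pos = rng.uniform(0, 8.0, size=(50, 3))
        pd = neighbor_pairs(pos, 8.0, 2.5)
        keys = list(zip(pd.i.tolist(), pd.j.tolist()))
        assert len(keys) == len(set(keys))
        assert all(i < j for i, j in keys)
        assert keys == sorted(keys)

    def test_box_too_small_rejected(self):
        with pytest.raises(ValueError, match="box"):
            neighbor_pairs(np.zeros((2, 3)), 3.0, 2.0)

    def test_verlet_list_equals_fresh_tree_after_motion(self, rng):
        box, R_cut = 8.0, 2.1564
        pos = rng.uniform(0, box, size=(80, 3))
        nlist = NeighborList(box, R_cut, skin=0.3)
        for _ in range(5):
            pos = np.mod(pos + rng.normal(0, 0.05, size=pos.shape), box)
            a = nlist.pairs(pos)
            b = neighbor_pairs(pos, box, R_cut)
            assert set(zip(a.i.tolist(), a.j.tolist())) == set(
                zip(b.i.tolist(), b.j.tolist())
            )


class TestConservativeForces:
    def test_newton_third_law_and_gradient_oracle(self, argon_tait, rng):
        """The pairwise force equals minus the gradient of the total internal
        energy at fixed entropies, by central finite differences.

        At fixed per-particle entropy the temperature part of u is constant,
        so the potential is U = sum_i Psi(n_i({r})); for the corrected
        estimator the chain rule through V(n^b) produces the zeta factor."""
        box = 7.0
        kernel = KernelConfig(R_cut=2.1564, f_cut=1.33, dim=3)
        tait = argon_tait
        # ten jittered sites at liquid-like spacing: every particle has
        # neighbors, densities stay near the reference value
        base = np.array(
            [[x, y, z] for x in (3.0, 4.0) for y in (3.0, 4.0) for z in (3.0, 4.0)]
            + [[3.5, 3.5, 2.2], [3.5, 2.2, 3.5]]
        )
        pos = base + rng.uniform(-0.1, 0.1, size=base.shape)

        for estimator in ("lde_a", "lde_b"):
            system = make_system(pos, box, tait, 0.0111, rng)
            pairs = neighbor_pairs(system.positions, box, kernel.R_cut)
            equilibrated_u(system, pairs, kernel, tait, estimator, 0.0111)
            f_pair, _, F = conservative_forces(system, pairs, kernel)

            # antisymmetry: net force vanishes
            np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-12)

            def total_potential(positions):
                from gendpde.local_density import density_fields, kernel_w

                p2 = neighbor_pairs(np.mod(positions, box), box, kernel.R_cut)
                w = kernel_w(p2.r, kernel)
                n_b = np.bincount(p2.i, weights=w, minlength=10) + np.bincount(
                    p2.j, weights=w, minlength=10
                )
                fields = density_fields(n_b, kernel, estimator)
                return float(np.sum(psi(fields.n, tait)))

            h = 1e-6
            for idx in (0, 3, 7):
                for axis in range(3):
                    shifted = pos.copy()
                    shifted[idx, axis] += h
                    up = total_potential(shifted)
                    shifted[idx, axis] -= 2 * h
                    down = total_potential(shifted)
                    grad = (up - down) / (2 * h)
                    assert -grad == pytest.approx(
                        F[idx, axis], rel=1e-6, abs=1e-9
                    ), f"{estimator} particle {idx} axis {axis}"

    def test_lde_a_equals_unit_zeta_form(self, argon_tait, rng):
        """With the raw estimator the force reduces bit-identically to the
        unit-zeta expression."""
        box = 7.0
        kernel = KernelConfig(R_cut=2.1564, f_cut=1.0, dim=3)
        pos = clustered_positions(rng, 20, center=3.5, side=1.8)
        system = make_system(pos, box, argon_tait, 0.0111, rng)
        pairs = neighbor_pairs(system.positions, box, kernel.R_cut)
        equilibrated_u(system, pairs, kernel, argon_tait, "lde_a", 0.0111)
        f_pair, _, _ = conservative_forces(system, pairs, kernel)

        from gendpde.local_density import kernel_w_prime

        coef = system.pi / system.fields.n**2
        cmag = -(coef[pairs.i] + coef[pairs.j]) * kernel_w_prime(pairs.r, kernel)
        np.testing.assert_array_equal(f_pair, cmag[:, None] * pairs.e)


class TestDissipativeAndRandom:
    def _pair_system(self, argon_tait, rng, same_velocity=False):
        box = 8.0
        pos = np.array([[3.0, 4.0, 4.0], [4.2, 4.0, 4.0]])
        v = np.array([[0.3, 0.1, -0.2], [0.3, 0.1, -0.2]]) if same_velocity else \
            np.array([[0.3, 0.1, -0.2], [-0.1, 0.2, 0.4]])
        kernel = KernelConfig(R_cut=2.1564, f_cut=1.33, dim=3)
        system = make_system(pos, box, argon_tait, 0.0111, rng, momenta=v)
        pairs = neighbor_pairs(system.positions, box, kernel.R_cut)
        equilibrated_u(system, pairs, kernel, argon_tait, "lde_b", 0.0111)
        return system, pairs, kernel

    def test_friction_vanishes_for_equal_velocities(self, argon_tait, rng):
        system, pairs, kernel = self._pair_system(argon_tait, rng, same_velocity=True)
        cfg = SimConfig(dt=1e-3, n_equil=0, n_production=0, gamma_star=2.14,
                        kappa_star=7.2e-4, target_T=0.0111)
        f_D, _ = dissipative_and_random_momentum(system, pairs, kernel, cfg, rng)
        np.testing.assert_allclose(f_D, 0.0, atol=1e-15)

    def test_random_impulse_variance(self, argon_tait, rng):
        """Sample variance of the pair impulse magnitude matches the
        fluctuation-dissipation amplitude (theta_i + theta_j) gamma_ij dt."""
        system, pairs, kernel = self._pair_system(argon_tait, rng)
        cfg = SimConfig(dt=1e-3, n_equil=0, n_production=0, gamma_star=2.14,
                        kappa_star=7.2e-4, target_T=0.0111)
        draws = 100_000
        samples = np.empty(draws)
        for trial in range(draws):
            _, dp_R = dissipative_and_random_momentum(system, pairs, kernel, cfg, rng)
            samples[trial] = dp_R[0] @ pairs.e[0]
        r = pairs.r[0]
        gamma_ij = cfg.gamma_star * (1 - r / kernel.R_cut) ** 2
        expected_var = (system.theta[0] + system.theta[1]) * gamma_ij * cfg.dt
        observed = samples.var()
        sigma = expected_var * math.sqrt(2.0 / draws)  # chi^2 spread
        assert abs(observed - expected_var) < 3 * sigma

    def test_pair_momentum_conservation_exact(self, argon_tait, rng):
        """Each pair impulse is applied equal-and-opposite: total is 0 exactly."""
        from gendpde.dynamics import _accumulate

        system, pairs, kernel = self._pair_system(argon_tait, rng)
        cfg = SimConfig(dt=1e-3, n_equil=0, n_production=0, gamma_star=2.14,
                        kappa_star=7.2e-4, target_T=0.0111)
        f_D, dp_R = dissipative_and_random_momentum(system, pairs, kernel, cfg, rng)
        total = _accumulate(f_D + dp_R, pairs.i, pairs.j, system.N).sum(axis=0)
        np.testing.assert_array_equal(total, 0.0)


class TestHeatExchange:
    def _system(self, argon_tait, rng, thetas):
        box = 8.0
        pos = np.array([[3.0, 4.0, 4.0], [4.2, 4.0, 4.0]])
        kernel = KernelConfig(R_cut=2.1564, f_cut=1.33, dim=3)
        system = make_system(pos, box, argon_tait, 0.0111, rng)
        pairs = neighbor_pairs(system.positions, box, kernel.R_cut)
        equilibrated_u(system, pairs, kernel, argon_tait, "lde_b", np.asarray(thetas))
        return system, pairs, kernel

    def test_no_flux_between_equal_temperatures(self, argon_tait, rng):
        system, pairs, kernel = self._system(argon_tait, rng, [0.0111, 0.0111])
        cfg = SimConfig(dt=1e-3, n_equil=0, n_production=0, gamma_star=2.14,
                        kappa_star=7.2e-4, target_T=0.0111)
        qdot, _ = heat_exchange(system, pairs, kernel, cfg, rng)
        np.testing.assert_allclose(qdot, 0.0, atol=1e-15)

    def test_heat_flows_hot_to_cold(self, argon_tait, rng):
        system, pairs, kernel = self._system(argon_tait, rng, [0.02, 0.01])
        cfg = SimConfig(dt=1e-3, n_equil=0, n_production=0, gamma_star=2.14,
                        kappa_star=7.2e-4, target_T=0.0111)
        qdot, _ = heat_exchange(system, pairs, kernel, cfg, rng)
        # particle 0 is hotter; the flux convention adds qdot to i: it loses heat
        assert qdot[0] < 0.0

    def test_random_energy_variance(self, argon_tait, rng):
        system, pairs, kernel = self._system(argon_tait, rng, [0.0111, 0.0111])
        cfg = SimConfig(dt=1e-3, n_equil=0, n_production=0, gamma_star=2.14,
                        kappa_star=7.2e-4, target_T=0.0111)
        draws = 100_000
        samples = np.empty(draws)
        for trial in range(draws):
            _, du_R = heat_exchange(system, pairs, kernel, cfg, rng)
            samples[trial] = du_R[0]
        r = pairs.r[0]
        kappa_ij = cfg.kappa_star * (1 - r / kernel.R_cut) ** 2
        expected_var = 2.0 * kappa_ij * cfg.dt
        observed = samples.var()
        sigma = expected_var * math.sqrt(2.0 / draws)
        assert abs(observed - expected_var) < 3 * sigma


class TestStep:
    def _config(self, seed=7, **kw):
        defaults = dict(dt=1e-3, n_equil=0, n_production=0, gamma_star=2.14,
                        kappa_star=7.2e-4, target_T=0.0111, seed=seed)
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_ballistic_motion_without_interactions(self, argon_tait, rng):
        """gamma = kappa = 0 and a force-free configuration: straight lines."""
        kernel = KernelConfig(R_cut=1.5, f_cut=1.33, dim=3)
        # two particles out of interaction range: no pairs at all
        pos = np.array([[1.0, 1.0, 1.0], [5.0, 5.0, 5.0]])
        mom = np.array([[0.2, -0.1, 0.05], [-0.2, 0.1, -0.05]])
        system = make_system(pos, 10.0, argon_tait, 0.0111, rng, momenta=mom)
        system.u = np.full(2, float(psi(1.0, argon_tait)) + argon_tait.CV * 0.0111)
        cfg = self._config(gamma_star=0.0, kappa_star=0.0)
        with pytest.raises(ValueError):
            # isolated particles have n_b = 0: the corrected density is the
            # inverse bare kernel volume, far below n_min, u < Psi -> error
            step(system, argon_tait, kernel, cfg, rng)

    def test_ballistic_motion_uniform_gas(self, argon_tait, rng):
        """Zero dissipative couplings and uniform density: the conservative
        forces cancel pairwise on the perfect lattice and motion is ballistic
        over one step."""
        kernel = KernelConfig(R_cut=2.1564, f_cut=1.33, dim=3)
        cfg = self._config(gamma_star=0.0, kappa_star=0.0)
        system = init_lattice_system(216, argon_tait, 0.0111, rng, jitter=0.0)
        system.momenta[:] = 0.013
        expected = np.mod(
            system.positions + system.momenta * cfg.dt, system.box
        )
        step(system, argon_tait, kernel, cfg, rng)
        np.testing.assert_allclose(system.positions, expected, atol=1e-12)

    def test_momentum_conserved_to_machine_precision(self, argon_tait, rng):
        kernel = KernelConfig(R_cut=2.1564, f_cut=1.33, dim=3)
        cfg = self._config()
        system = init_lattice_system(216, argon_tait, 0.0111, rng)
        p0 = system.momenta.sum(axis=0)
        for _ in range(50):
            step(system, argon_tait, kernel, cfg, rng)
        assert np.abs(system.momenta.sum(axis=0) - p0).max() < 1e-12

    def test_energy_exact_after_drift_correction(self, argon_tait, rng):
        kernel = KernelConfig(R_cut=2.1564, f_cut=1.33, dim=3)
        cfg = self._config()
        system = init_lattice_system(216, argon_tait, 0.0111, rng)
        step(system, argon_tait, kernel, cfg, rng)  # sets derived fields
        E_ref = system.total_energy()
        for _ in range(50):
            report = step(system, argon_tait, kernel, cfg, rng)
        assert system.total_energy() == pytest.approx(E_ref, rel=1e-12)
        # pre-correction drift is small compared to the total energy
        assert abs(report.drift) / abs(report.E_total) < 1e-5

    def test_deterministic_given_seed(self, argon_tait):
        kernel = KernelConfig(R_cut=2.1564, f_cut=1.33, dim=3)
        results = []
        for _ in range(2):
            cfg = self._config(seed=42)
            rng = np.random.Generator(np.random.Philox(cfg.seed))
            system = init_lattice_system(125, argon_tait, 0.0111, rng)
            for _ in range(20):
                step(system, argon_tait, kernel, cfg, rng)
            results.append((system.positions.copy(), system.momenta.copy(),
                            system.u.copy()))
        for a, b in zip(results[0], results[1]):
            np.testing.assert_array_equal(a, b)

    def test_unphysical_internal_energy_fails_loudly(self, argon_tait, rng):
        kernel = KernelConfig(R_cut=2.1564, f_cut=1.33, dim=3)
        cfg = self._config(dt=5.0)  # absurd time step
        system = init_lattice_system(125, argon_tait, 0.0111, rng)
        with pytest.raises((RuntimeError, ValueError)):
            for _ in range(10):
                step(system, argon_tait, kernel, cfg, rng)


class TestTuneFCut:
    def test_pilot_bisection_reaches_reference_density(self, argon_tait):
        """The reconstruction helper finds a volume-correction factor whose
        pilot-run mean density matches n0 within its stated tolerance."""
        from gendpde.dynamics import tune_f_cut

        cfg = SimConfig(dt=1e-3, n_equil=0, n_production=0, gamma_star=2.14,
                        kappa_star=7.2e-4, target_T=0.011069, seed=13)
        f_cut = tune_f_cut(argon_tait, 2.1564, cfg, N=216,
                           n_pilot=(500, 500), tol=0.01, max_iter=5)
        assert 1.0 < f_cut < 2.0
        kernel = KernelConfig(R_cut=2.1564, f_cut=f_cut, dim=3)
        pilot = SimConfig(dt=1e-3, n_equil=500, n_production=500,
                          gamma_star=2.14, kappa_star=7.2e-4,
                          target_T=0.011069, seed=13)
        res = run_simulation(argon_tait, kernel, pilot, N=216,
                             collect_frames=False)
        assert float(res.series["n_mean"].mean()) == pytest.approx(1.0, abs=0.02)

    def test_non_bracketing_bounds_rejected(self, argon_tait):
        from gendpde.dynamics import tune_f_cut

        cfg = SimConfig(dt=1e-3, n_equil=0, n_production=0, gamma_star=2.14,
                        kappa_star=7.2e-4, target_T=0.011069, seed=13)
        with pytest.raises(ValueError, match="bracket"):
            tune_f_cut(argon_tait, 2.1564, cfg, N=216, n_pilot=(200, 200),
                       bounds=(1.9, 2.0))


class TestRunSimulation:
    def test_short_run_reproducible_and_sane(self, argon_tait):
        kernel = KernelConfig(R_cut=2.1564, f_cut=1.33, dim=3)
        cfg = SimConfig(dt=1e-3, n_equil=50, n_production=100, gamma_star=2.14,
                        kappa_star=7.2e-4, target_T=0.0111, seed=3,
                        sample_every=10, rdf_every=50)
        res1 = run_simulation(argon_tait, kernel, cfg, N=125)
        res2 = run_simulation(argon_tait, kernel, cfg, N=125)
        assert res1.series.equals(res2.series)
        assert res1.series["n_mean"].iloc[-1] == pytest.approx(1.0, abs=0.1)
        assert (res1.series["T_kin"] > 0).all()
        assert len(res1.rdf_frames) == 2
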