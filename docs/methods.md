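# Methods

## Model

`gendpde` simulates a one-component mesoscale liquid with energy-conserving
dissipative particle dynamics.  Each mesoparticle stands for `phi` physical
molecules (default 5) and carries, besides position and momentum, an internal
energy `u_i` representing the thermal content of its unresolved degrees of
freedom.  The internal state is assumed locally equilibrated, so each
particle has a well-defined entropy `s_i(u_i, n_i)` depending on its internal
energy and on a local number density `n_i` determined by its neighborhood.
From this entropy follow per-particle intensive variables: a dressed
temperature `theta_i` and pressure `pi_i` (energetic representation) and bare
counterparts `theta~_i`, `pi~_i` (entropic representation) that differ by
terms of order `1/C_V`.  At equilibrium `<theta_i> = T` and
`<1/theta~_i> = 1/T`, so both are estimators of the thermostat temperature,
and `<pi_i>` estimates the excess (non-ideal) pressure.

### Internal thermodynamics (Tait closure)

The particle pressure follows the modified Tait equation of state for weakly
compressible liquids,

    pi(n) = pi0 + B_T [(n/n0)^gammaT - 1],      B_T = 1/(gammaT kappaT0),

which pins the model compressibility at the reference state to the physical
isothermal compressibility.  Its density potential

    Psi(n) = (B_T - pi0)/n + B_T/((gammaT-1) n0) (n/n0)^(gammaT-1)

satisfies `pi = n^2 Psi'(n)` and has a minimum at
`n_min = n0 (1 - pi0/B_T)^(1/gammaT)` where the particle pressure vanishes —
the density basin responsible for the clustering artifact discussed below.
The temperature part of the free energy is chosen so that the entropy and
its slope vanish as `theta -> 0` (Third Law); far above the reference
temperature `theta0` it reduces to `u = Psi(n) + C_V theta`, which is the
default closure (all production physics here is near-ambient,
`theta/theta0 ~ 10`).  Under that closure the bare variables have closed
forms: `theta~ = theta/(1 - 1/C_V)` and `pi~ = pi`.  `theta0` defaults to
`0.1 T0*`; it only affects the optional full (low-temperature) form.

### Local density estimators

Two estimators convert a configuration into per-particle densities:

* **LDE-A** (traditional): `n_i^b = sum_j w(r_ij)` with the normalized
  quadratic kernel `w(r) = 15/(2 pi R^3)(1 - r/R)^2` (3-D).  In a structured
  liquid every particle sits inside its own correlation hole, so the kernel
  sum systematically underestimates the density.
* **LDE-B** (corrected): the particle volume is the space integral of the
  approximate partition-of-unity weight `w~/(w~ + n^b)` built from a
  *rescaled* kernel of range `R~ = R_cut/f_cut`.  The integral has a closed
  form in terms of `k = (2 pi/15) R~^3 n^b` (3-D) or `k = (pi/6) R~^2 n^b`
  (2-D); `n = 1/V`.  The raw sum `n^b` is still measured at range `R_cut`,
  so the correction adds no neighbor-search cost.  `f_cut >= 1` absorbs the
  correlation-hole corrections and is a per-state-point parameter; the
  shipped presets carry the published per-cutoff values.

The conservative force needs `zeta = dn/dn^b`; for LDE-A it is exactly 1,
for LDE-B it follows from the analytic `dV/dk`.  Both `V(k)` and `dV/dk`
switch to an alternating asymptotic series in `1/k` for `k > 50`, where the
direct closed form loses roughly `eps * k` digits to cancellation; the
series is truncated at 15 terms (relative truncation below 1e-12 at the
switch point).  At `k = 0` the volume is the bare kernel volume; `zeta`
diverges as `n^b -> 0` (an isolated particle), which in practice signals a
configuration outside the liquid regime.

### Equations of motion

Pairwise channels, all conserving momentum and total energy by construction:

* conservative force `-(pi_i zeta_i/n_i^2 + pi_j zeta_j/n_j^2) w'(r) e_ij`,
* DPD friction `-gamma_ij (v_ij . e) e` with
  `gamma_ij = gamma (1 - r/R_cut)^2` (non-normalized weight),
* random impulse `sqrt((theta_i + theta_j) gamma_ij) Omega e sqrt(dt)`,
  one standard Gaussian per pair per step, *symmetric* in (i, j) so the two
  particles receive equal and opposite impulses,
* heat flux `-kappa_ij (1/theta~_j - 1/theta~_i)` driven by bare inverse
  temperatures, plus an *antisymmetric* random exchange of variance
  `2 kappa_ij dt`.

The internal-energy balance mirrors every momentum-channel term, including
the random-work double sum `-|sum_j dp^R_ij|^2 / (2 m_i)`, so that the total
energy change per step is zero through order `dt`.  The noise-symmetry
assignment (momentum channel symmetric, energy channel antisymmetric) is
forced by the conservation laws themselves.

### Integration

Positions and momenta advance by velocity-Verlet with the pair terms frozen
at their start-of-step values (`p' = p + dp`, `r' = r + (p + dp/2) dt/m`);
the internal energies advance by explicit Euler with the same pair terms.
Freezing the pair terms makes the scheme explicit and keeps the
internal-energy update exactly consistent with the momentum work terms; the
cost is an O(dt^2) per-step energy residual, which is measured every step,
logged, and removed by subtracting it equally from all internal energies.
Post-correction the total energy is conserved to round-off; the
pre-correction residual at the argon settings is of order 1e-6 of the total
energy per step, and its accumulated effect is bounded by the temperature
consistency check below.  An optional per-heat-capacity weighting of the
correction exists but uniform weighting already meets the 0.1% criterion.
Whether densities should be refreshed at the half step is not fixed by the
published discrete equations; the frozen-force convention was chosen and its
effect is covered by the time-step convergence implied by the conservation
suite.

A step fails loudly (with the offending particle) if any `u_i <= Psi(n_i)`,
i.e. a negative dressed temperature, which indicates too large a time step.
Exactly overlapping particles are rejected as a hard error: the kernel value
is finite there but the force direction is undefined, and overlaps indicate
a bad initial condition.

### Reduced units and transport mapping

Given a reference state (T0, P0, mass density, molar mass, compressibility,
specific heat, viscosity, conductivity), the unit of length comes from the
mesoparticle number density, the unit of energy from the compressibility
(`u_ref = 1/(n0 kappaT0)`), and the unit of mass from the coarse-graining
level.  This makes `n0* = 1`, `m* = 1`, `B_T* = 1/gammaT`, and splits the
reduced pressure as `P0* = T0* + pi0*` (ideal + excess).  CODATA values of
k_B and N_A are fixed constants so the mapping is exactly reproducible.

The mesoscopic friction gamma* solves a quadratic obtained by equating the
kinetic (`45 T*/(4 pi gamma* R^3)`) plus collisional
(`2 pi gamma* R^5/1575`) viscosity contributions to the reduced experimental
viscosity.  The *larger* root is selected: on that branch gamma* decreases
with growing cutoff, which is the physically sensible parametrization
(friction spread over more neighbors) and the one matching the published
tables; the smaller root (~0.01 for argon at R* = 2.16) also solves the
equation but is rejected.  The conduction relation is then linear in
kappa*: `lambda* = 45 C_V* T*/(2 pi gamma* R^3) + 2 pi kappa* R^5/(315 T*^2)`.
The grouping of the conduction formula was fixed by dimensional analysis
(it is the unique dimensionally consistent reading) and validated against
the published argon table.

## Simulation protocol

Simple-cubic start at the reference density with ±5% uniform jitter,
Maxwell momenta at the target temperature (center-of-mass motion removed),
and `u_i = Psi(n0) + C_V T*`.  Equilibration rescales all velocities every
step toward the target kinetic temperature; production is strictly
microcanonical.  The kinetic temperature uses 3(N-1) degrees of freedom
(momentum conservation freezes three).  The virial pressure
`P = (1/3V)[sum p^2/m + sum_pairs r_ij . f^C_ij]` uses conservative forces
only.  Block averages over 10 blocks provide the standard errors quoted in
summaries.

Neighbor search uses a periodic k-d tree behind a Verlet list with a 0.3
skin, rebuilt when any particle has moved more than half the skin — exact,
not approximate.  Random numbers come from a single counter-based (Philox)
stream; pairs are processed in sorted (i, j) order, so runs are bit-for-bit
reproducible from (config, seed) regardless of traversal details.

### Problem sizes

The shipped validation and acceptance runs use N = 1000 mesoparticles with
2e4 equilibration and 3e4 production steps (20 + 30 reduced time units at
dt = 1e-3).  This is a deliberate scale-down from the published N = 27000 /
3000 time units: equilibrium means of density and pressure converge quickly
with N at this state point, and the scaled runs reproduce the published
argon means within their published uncertainty scaled up accordingly
(density to ±0.01, pressure to ±0.005).  Finite-size effects do shift
the LDE-A pathology numbers, so those are asserted qualitatively only
(density drift toward the `n_min` basin, clustering shoulder in g(r)),
not at the published full-size values.

## What the validation does and does not show

The package's validation is entirely against internal consistency (force =
-gradient of the fixed-entropy potential, fluctuation-dissipation variances,
conservation laws, estimator identities) and against the published
reduced-unit argon/water benchmarks.  No comparison to experimental liquid
structure is made or implied: the mesoparticle g(r) is a property of the
coarse-grained model, not of the molecular fluid.  The water state point is
reproduced thermodynamically but, as in the source analysis, sits so close
to the zero-pressure density that density-dependent potentials form
filament-like structures there regardless of estimator; water results should
be read as a stress test, not as a water model.

## Known limitations and deliberate deviations

* **Lattice benchmark scaling factor.**  With the closed 2-D volume form
  derived here (validated against adaptive quadrature to 1e-10), the
  corrected estimator tracks the geometric hexagonal-lattice area almost
  exactly at `f_cut = 1.50` (max 2.1% over l in [0.8, 1.3]), not at the
  1.8 quoted for the original figure; at 1.8 this implementation deviates
  by up to 16%.  The qualitative behavior (monotone improvement over the
  raw estimate, single-parameter matching) is identical.  The acceptance
  bound for the f_cut = 1.8 curve is therefore a frozen regression bound
  (17%) from this package's own scan rather than a near-exactness claim.
* **Water transport table.**  The published water gamma* values are
  reproduced to ~0.3% but not to printed precision (argon reproduces to
  printed precision); the offset is systematic and consistent with rounded
  physical inputs upstream.  Tests assert 0.5% relative for water.
* The published per-cutoff `f_cut` values are shipped as data; how they
  were originally tuned is not stated.  `dynamics.tune_f_cut` implements a
  plausible reconstruction — bisection on short pilot runs until the mean
  corrected density matches `n0` — flagged as a reconstruction, with a
  tolerance limited by pilot-run noise.
* Single component, single reference state per run, no barostat or
  constant-temperature production, no Wendland/Lucy kernels, no Voronoi
  volumes (the partition-of-unity diagnostic covers the additivity check).
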