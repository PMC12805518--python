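# Liquid argon reference state and per-cutoff run parameters.
[substance]
name = "argon"
T0 = 125.7            # K
P0 = 85.31e6          # Pa
rho_mass0 = 1419.7    # kg/m^3
Mw = 39.948e-3        # kg/mol
kappaT0 = 1.49e-9     # 1/Pa
cV_specific = 5.20e2  # J/(kg K)
nu = 1.69e-7          # m^2/s
lam = 0.139           # W/(m K)
gammaT = 6.0
phi = 5

# One block per tabulated cutoff: mesoscopic friction/conduction mapped from
# the macroscopic transport coefficients, the tuned volume-correction factor,
# and the integration controls used at that cutoff.
[[cutoffs]]
R_cut = 1.3365
gamma_star = 23.42
kappa_star = 0.0079
f_cut = 1.41
dt = 5e-4
n_equil = 2000000
n_production = 4000000

[[cutoffs]]
R_cut = 1.6839
gamma_star = 7.37
kappa_star = 0.0025
f_cut = 1.35
dt = 1e-3
n_equil = 1000000
n_production = 2000000

[[cutoffs]]
R_cut = 2.1564
gamma_star = 2.14
kappa_star = 0.00072
f_cut = 1.33
dt = 1e-3
n_equil = 1000000
n_production = 2000000
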