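# Liquid water near-ambient reference state and per-cutoff run parameters.
[substance]
name = "water"
T0 = 293.16           # K
P0 = 0.10e6           # Pa
rho_mass0 = 998.20    # kg/m^3
Mw = 18.015e-3        # kg/mol
kappaT0 = 4.60e-10    # 1/Pa
cV_specific = 4.15e3  # J/(kg K)
nu = 1.00e-6          # m^2/s
lam = 0.598           # W/(m K)
gammaT = 5.0
phi = 5

[[cutoffs]]
R_cut = 1.3365
gamma_star = 75.20
kappa_star = 0.015
f_cut = 1.00
dt = 5e-5
n_equil = 20000000
n_production = 40000000

[[cutoffs]]
R_cut = 1.6839
gamma_star = 23.68
kappa_star = 0.0047
f_cut = 1.01
dt = 1e-4
n_equil = 10000000
n_production = 20000000

[[cutoffs]]
R_cut = 2.1564
gamma_star = 6.88
kappa_star = 0.0014
f_cut = 1.18
dt = 1e-4
n_equil = 10000000
n_production = 20000000

[[cutoffs]]
R_cut = 2.4286
gamma_star = 3.79
kappa_star = 0.00075
f_cut = 1.21
dt = 1e-4
n_equil = 10000000
n_production = 20000000
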