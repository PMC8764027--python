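# Frozen default parameters of the cross-feeding serial-transfer simulator.
#
# None of these constants are measured for the experimental strains; they
# were calibrated once against the qualitative behaviour of the system and
# are not tuned per run:
#   - a 100 µM amino-acid supplement supports growth of a monoculture to
#     roughly the carrying capacity (consumption = 0.10 µmol per 1e9 cells
#     in the 1-ml batch equals 100 µM per 1e9 cells/ml);
#   - unsupplemented cocultures bootstrap growth from a small carryover
#     pool and stay production-limited, hence slower and lower-yield;
#   - bactericidal ramps overwhelm the slow-growing coculture while
#     monocultures acquire stepwise resistance;
#   - under bacteriostatic stress, reversion to prototrophy is strongly
#     favoured in cocultures (pool-limited g_aa) but nearly neutral in
#     supplemented monocultures.
# See docs/methods.md for the reasoning behind each value.

growth_rate:        # maximal specific growth rate, h^-1 (30 degC, minimal medium)
  TRP: 0.50
  TYR: 0.50
k_aa: 20.0          # Monod constant of the required amino acid, µM
production: 0.30    # µmol partner amino acid released per 1e9 new cells
consumption: 0.10   # µmol required amino acid consumed per 1e9 new cells
capacity: 1.0e+9    # carrying capacity, cells/ml (OD600 ~ 1.0)
kappa: 2.0          # pharmacodynamic Hill exponent
mic0:               # ancestral per-cell MIC, µg/ml (about 2x the culture sub-MIC)
  AMP: 1.5
  CHL: 6.5
  KAN: 2.5
  TET: 2.7
  NONE: .inf
mode:
  AMP: bactericidal
  KAN: bactericidal
  CHL: bacteriostatic
  TET: bacteriostatic
  NONE: bacteriostatic
delta_max: 0.8      # maximal kill rate of bactericidal antibiotics, h^-1
mu_res: 1.0e-5      # per-division probability of one resistance step
mic_multiplier: 2.0 # MIC fold-change per resistance level
n_levels: 8         # maximal resistance level (MIC up to mic0 * 2^8)
mu_rev: 4.0e-11     # per-division probability of reversion to prototrophy
od_per_1e9: 1.0     # OD600 per 1e9 cells/ml
od_noise: 0.05      # lognormal sigma of the OD readout
batch_hours: 72.0
dt: 0.1             # integration step, h
inoculum_od: 0.1    # preculture density before inoculation
init_pool_co: 1.0   # µM amino-acid carryover in freshly inoculated cocultures
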