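# Methods

`muevolab` implements the computational workflow of an antibiotic-ramping
serial-transfer evolution experiment on an obligate cross-feeding
*Escherichia coli* mutualism: two auxotrophic strains — a tryptophan
auxotroph (TRP) and a tyrosine auxotroph (TYR) — that reciprocally exchange
the amino acid their partner cannot make. Supplemented monocultures of the
same strains serve as the non-mutualistic control. This note documents the
models, the numerical choices, and what the synthetic-data generator does
and does not emulate.

## Experiment design and ramp

The design is a full factorial of three culture types (TRP monoculture,
TYR monoculture, coculture) by four antibiotics (ampicillin, kanamycin,
chloramphenicol, tetracycline), with 16 founder lineages each split into 5
technical replicates, i.e. 80 replicates per treatment cell. Monocultures
are supplemented with both amino acids at 100 µM; cocultures are not.
Cultures grow for 72 h per transfer and are diluted 1:25 (40 µl into
960 µl) for 15 transfers.

The ramp has two antibiotic-free transfers, a doubling phase from
one-eighth of the sub-MIC at transfer 2 up to the sub-MIC at transfer 5,
and a linear phase with constant increment up to the endpoint at transfer
15. "Slightly above the working concentration" is quantified as
`end_factor * working_conc` with `end_factor = 1.1`, the smallest round
margin consistent with that description; it is configurable. The doubling
phase is fixed at four steps, which follows from the one-eighth starting
point; the first transfer *above* sub-MIC is therefore transfer 6.

### Sub-MIC rules

The sub-MIC is read off a dose-response plate with a threshold zone of
OD600 0.05 ± 0.005, closed at both endpoints ("± " read as inclusive).
Scanning concentrations in ascending order: one fully contained
concentration wins; several fully contained are averaged; a partial
overlap is averaged with the next measured concentration, or kept as is
when it is the last one. When the concentration after a partial overlap is
itself partially inside the zone — a case the verbal rules do not
enumerate — the same mean-of-the-two formula is applied.

## The cross-feeding simulator

The generator is a hybrid stochastic serial-transfer model. State is the
cell count per genotype class — strain × discrete resistance level
(`MIC = mic0 · λ^ℓ`, λ = 2, ℓ ≤ 8) × prototrophy flag — plus the two free
amino-acid pools (µM). Within a 72-h batch each class grows at

    mu = r · g_aa · g_ab · (1 − N_tot / C)

with `g_aa = [AA]/(K_aa + [AA])` for auxotrophs (1 for prototrophs) and
the pharmacodynamic factor `g_ab = 1/(1 + (conc/MIC)^κ)`. Bactericidal
antibiotics (AMP, KAN) additionally kill at
`δ_max · (conc/MIC)^κ/(1 + (conc/MIC)^κ)`; bacteriostatic ones (CHL, TET)
only suppress growth. Divisions release the partner amino acid
(`production` µmol per 10⁹ new cells) and consume the required one
(`consumption`); in the 1-ml batch, 1 µmol moves the pool by 1000 µM.
Monocultures receive the 100 µM supplement at the start of each batch.
Resistance steps (ℓ → ℓ+1) and reversion to prototrophy are drawn Poisson
from per-step division counts (τ-leap style); the deterministic mode takes
expected values instead and suppresses OD noise. The OD600 readout is
`N_tot/10⁹` with multiplicative lognormal noise (σ = 0.05).

### Numerical scheme

The continuous dynamics integrate with a fixed-step Heun (second-order)
method at dt = 0.1 h, with mutation sampling after each step and state
clipped at zero. The second-order scheme matters: the coculture's 72-h
density sits on a steeply accelerating part of its growth curve, where a
first-order step carries a visible timing error. Halving the default step
changes deterministic 72-h densities by < 0.1% (monoculture ≪ coculture).
All stochastic draws derive child seeds from
`(global seed, operation name, treatment group)`, so results are
reproducible and independent of the order in which groups are simulated;
the dynamics of a treatment's replicates are vectorised in one array, so
seeding is per group rather than per lineage.

### Parameter calibration (frozen defaults)

No kinetic constants are published for these strains; every default in
`src/muevolab/data/default_params.yaml` is a one-time calibration choice,
frozen thereafter:

- `r = 0.5 h⁻¹`, `C = 10⁹ cells/ml` (OD600 ≈ 1.0): typical minimal-medium
  growth at 30 °C.
- `consumption = 0.10 µmol / 10⁹ cells`: makes the 100 µM supplement
  support a monoculture to approximately the carrying capacity, consistent
  with the supplemented design.
- `production = 0.30`, `K_aa = 20 µM`, 1 µM carryover pool: the coculture
  bootstraps slowly from the diluted pool (~20–35 h of strongly limited
  growth per batch), then accelerates as the pools build. A fresh coculture
  inoculated from precultures reaches only ~40% of the monoculture's
  72-h density with its steepest growth late (66–72 h vs 12–15 h for
  monocultures), while the serial-transfer steady state is stable. The
  production surplus is what keeps successive transfers from starving: with
  a smaller surplus the diluted pool cannot restart the next batch and the
  coculture spirals to extinction even without antibiotics.
- `mic0` ≈ 2× the culture-level sub-MIC per antibiotic. Note that the
  *culture-level* MIC (OD threshold after 72 h of compounded growth) is
  sharper and lower than the per-cell `mic0`.
- `κ = 2`, `δ_max = 0.8 h⁻¹`: a moderate Hill slope and a kill rate that
  overwhelms bootstrap-phase coculture growth (~0.1 h⁻¹) but not
  supplemented monoculture growth (~0.45 h⁻¹).
- `µ_res = 10⁻⁵` per division: lets monocultures climb the resistance
  ladder roughly one level per transfer, tracking the linear ramp. The
  coculture usually cannot: its antibiotic-sensitive majority collapses
  during the slow bootstrap phase, and a rescue requires *both* partner
  strains to carry enough resistance simultaneously.
- `µ_rev = 4·10⁻¹¹` per division: reversion events are rare (~0.1–0.5 per
  replicate over the experiment). In the coculture a revertant escapes the
  amino-acid bottleneck and sweeps within a few transfers; in supplemented
  monocultures the advantage is marginal (Monod factor 0.83 → 1) and
  revertants stay at mutation-selection frequencies. This selection
  asymmetry — not a rate asymmetry — is what produces the excess of
  coevolved revertants.

The ancestral assay generators (growth kinetics, MIC plates) run with
mutation flows off: a single 72-h batch is too short for mutants to matter,
and the expected-value deterministic mode would otherwise amplify
fractional mutant "cells" exponentially, an artifact of taking expectations
inside exponential growth. For the same reason the deterministic mode of
the full evolution experiment is intended for contract checks, not for
evolutionary inference.

### What the generator does not emulate

Spatial structure and multicellular cluster feedbacks, genome-scale
metabolism, horizontal gene transfer, plate-reader artefacts, and
between-batch environmental drift. Passing direction-of-effect tests shows
the pipeline responds correctly to data with the qualitative structure of
the experiment; it does not validate the kinetic constants against the
real strains.

## Analysis stages

- **Growth**: replicate curves are averaged per time point; the pair of
  consecutive grid times with the maximal raw increase of the mean curve
  fixes the interval; each replicate's maximum growth rate is then the
  log-slope over that interval (the raw slope is emitted alongside, since
  "maximum growth rate" can be read either way). A consequence of
  selecting by raw increase is that the interval can fall after the
  specific growth rate has peaked.
- **MIC**: first concentration with OD600 < 0.01, censored above the grid;
  ΔMIC subtracts the ancestral group *median* from each derived replicate
  (groups are unpaired by design). Censored values are excluded with a
  warning.
- **Group comparisons**: two-sided Mann-Whitney U (exact for n ≤ 8 without
  ties, normal approximation with tie correction otherwise),
  Benjamini-Hochberg step-up correction, and a compact letter display built
  from maximal cliques of the non-significance graph, so two groups share a
  letter iff their adjusted p ≥ α (default 0.05).
- **Survival**: extinction at the first transfer with OD600 strictly below
  0.01 (a reading exactly at the threshold is alive); survivors censored at
  transfer 15. Kaplan-Meier estimation and pairwise log-rank tests are
  delegated to lifelines; the test suite cross-checks the log-rank
  statistic against an independent hypergeometric accumulation. Time is the
  transfer index — the experiment's sampling resolution — with standard
  tied-event variance. The 72-h pre-dilution OD defines death.
- **Clustering**: per-lineage OD profiles over transfers 0–15, with
  post-extinction entries imputed as 0 (a dead culture has no density; this
  keeps every replicate in the tree) and no per-column standardisation
  (absolute density differences are the signal). Clustering is a Gaussian
  mixture with diagonal covariances and a 10⁻⁶ variance floor, best of 10
  EM starts per K, K selected by minimum BIC — a deterministic, equivalent
  stand-in for a variational mixture on well-separated data. The tree is a
  Ward hierarchy on Euclidean distances, exported as Newick.
- **Composition test**: the statistic is the maximum over clusters with at
  least 5 members of (focal-group count × focal fraction), i.e. count²/size;
  the size floor prevents singleton-purity artefacts. The null permutes
  group labels uniformly across lineages (default 10⁶ permutations,
  vectorised in chunks), and the add-one estimator
  p = (1 + #{T* ≥ T_obs})/(1 + N) never returns zero, so the smallest
  attainable p is 1/(N+1) ≈ 10⁻⁶.
- **Reversion**: colonies are classified from growth flags on MMAB,
  MMAB+Trp, MMAB+Tyr and LB; growth on all four marks a revertant, growth
  only with the required amino acid the surviving auxotroph, anything else
  ambiguous (excluded from denominators but counted). Groups with zero
  detected revertants are reported as below the 2.5·10⁴ CFU/ml detection
  limit, never as frequency zero. Group ratios are compared with a plain
  Pearson χ² (df = 1, no continuity correction).

## Problem sizes

The repeated-seed direction-of-effect checks and the seeded acceptance
runs use 8 lineages × 2 technical replicates (16 per treatment cell) over
the full 15-transfer ramp, and 10 seeds per direction; these sizes give
stable directions (10/10 seeds in calibration) while keeping the whole
suite at desk scale. The million-permutation composition test runs at full
size. Cluster-recovery calibration uses 120-row, 3-dimensional planted
partitions, where BIC reliably selects the planted number of components.

## Known limitations

- The simulator's coculture steady state sits at carrying capacity; the
  growth deficit of the mutualism shows in assay-style batches from fresh
  inocula, not in the late serial-transfer ODs.
- Resistance is a discrete MIC ladder with a fixed multiplier; continuous
  resistance distributions and fitness costs of resistance are not
  modelled (reversion cost is configurable but zero by default).
- The compact letter display is a greedy clique cover; with many groups a
  minimal letter set is not guaranteed, only correctness of sharing.
- Culture-level MIC and sub-MIC emerge from 72-h compounded growth and are
  therefore lower than the per-cell pharmacodynamic MIC parameter; the two
  should not be conflated when setting `mic0`.
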