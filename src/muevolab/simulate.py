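"""Stochastic serial-transfer simulator of a cross-feeding coculture.

Two *E. coli* auxotrophs are modelled: a tryptophan auxotroph (TRP) that
over-produces tyrosine, and a tyrosine auxotroph (TYR) that over-produces
tryptophan. In unsupplemented coculture each strain's growth is
Monod-limited by the amino-acid pool its partner releases; supplemented
monocultures draw on a 100 µM external supply instead.

Within a 72-h batch, each genotype class (strain x discrete resistance
level x prototrophy flag) grows at

    mu = r * g_aa * g_ab * (1 - N_tot / C)

with ``g_aa = [AA] / (K_aa + [AA])`` for auxotrophs (1 for prototrophs) and
the pharmacodynamic inhibition ``g_ab = 1 / (1 + (conc / MIC)**kappa)``,
where a class at resistance level ``l`` has ``MIC = mic0 * lambda**l``.
Bactericidal antibiotics additionally kill at rate
``delta_max * (conc/MIC)**kappa / (1 + (conc/MIC)**kappa)``.

Divisions release the partner amino acid (``production`` µmol per 1e9 new
cells) and consume the required one (``consumption`` µmol per 1e9 new
cells); resistance (level l -> l+1) and reversion to prototrophy arise from
division counts with small per-division probabilities, sampled Poisson per
integration step (tau-leap style) or taken at expectation in deterministic
mode. Integration uses a fixed 0.1-h explicit step; state is vectorised
across the replicates of a treatment so a whole treatment cell integrates
in one pass.

None of the kinetic constants below are measured quantities; they are
calibrated once to the qualitative behaviour of the experimental system
(see ``data/default_params.yaml`` and docs/methods.md) and frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .config import ANTIBIOTICS, STRAINS, TIME_GRID_H, RunConfig, child_rng
from .design import ExperimentDesign, RampSchedule

BACTERICIDAL = frozenset({"AMP", "KAN"})

#: strain axis order; index 0 requires Trp (pool 0), index 1 requires Tyr (pool 1)
STRAIN_INDEX = {"TRP": 0, "TYR": 1}


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimParams:
    """Kinetic and pharmacodynamic parameters of the simulator.

    Units: rates h^-1, pools µM, production/consumption µmol per 1e9 new
    cells (in the 1-ml batch volume, 1 µmol released raises the pool by
    1000 µM), capacity cells/ml, MICs µg/ml.
    """

    growth_rate: dict = field(
        default_factory=lambda: {"TRP": 0.50, "TYR": 0.50})
    k_aa: float = 20.0                 # Monod constant for the required amino acid
    production: float = 0.15           # µmol partner amino acid per 1e9 new cells
    consumption: float = 0.10          # µmol required amino acid per 1e9 new cells
    capacity: float = 1.0e9            # cells/ml
    kappa: float = 2.0                 # pharmacodynamic Hill exponent
    mic0: dict = field(default_factory=lambda: {
        "AMP": 1.5, "CHL": 6.5, "KAN": 2.5, "TET": 2.7, "NONE": np.inf})
    mode: dict = field(default_factory=lambda: {
        "AMP": "bactericidal", "KAN": "bactericidal",
        "CHL": "bacteriostatic", "TET": "bacteriostatic",
        "NONE": "bacteriostatic"})
    delta_max: float = 0.8             # h^-1, bactericidal maximal kill rate
    mu_res: float = 5.0e-6             # per-division resistance step probability
    mic_multiplier: float = 2.0        # MIC factor per resistance level
    n_levels: int = 8                  # maximal resistance level
    mu_rev: float = 2.0e-7             # per-division reversion to prototrophy
    od_per_1e9: float = 1.0            # OD600 per 1e9 cells/ml
    od_noise: float = 0.05             # lognormal sigma on the OD readout
    batch_hours: float = 72.0
    dt: float = 0.1                    # h, fixed integration step
    inoculum_od: float = 0.1           # preculture OD before inoculation
    init_pool_co: float = 2.0          # µM carryover pool in fresh cocultures

    def __post_init__(self) -> None:
        if self.mic_multiplier <= 1:
            raise ValueError("mic_multiplier must exceed 1")
        for name in ("k_aa", "production", "consumption", "capacity",
                     "kappa", "delta_max", "od_per_1e9", "batch_hours", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.mu_res <= 1 or not 0 <= self.mu_rev <= 1:
            raise ValueError("mutation probabilities must lie in [0, 1]")

    @classmethod
    def default(cls) -> "SimParams":
        """The frozen default parameter file shipped with the package."""
        text = resources.files("muevolab.data").joinpath(
            "default_params.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "SimParams":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulator parameters: {sorted(unknown)}")
        kwargs = dict(raw)
        if "mic0" in kwargs:
            kwargs["mic0"] = {k: (np.inf if v in ("inf", ".inf", None) else float(v))
                              for k, v in kwargs["mic0"].items()}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


@dataclass
class PopulationState:
    """Batched population state of one treatment's replicates.

    ``counts`` has shape (n_replicates, 2 strains, n_levels+1, 2), the last
    axis being the prototrophy flag (0 = auxotroph, 1 = prototroph);
    ``pools`` has shape (n_replicates, 2) holding the free [Trp] and [Tyr]
    concentrations in µM.
    """

    counts: np.ndarray
    pools: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.pools = np.asarray(self.pools, dtype=float)
        if (self.counts < 0).any() or (self.pools < 0).any():
            raise ValueError("counts and pools must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    def total(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2, 3))

    def strain_total(self, strain: str) -> np.ndarray:
        return self.counts[:, STRAIN_INDEX[strain]].sum(axis=(1, 2))

    def prototroph_fraction(self, strain: str) -> np.ndarray:
        s = STRAIN_INDEX[strain]
        tot = self.counts[:, s].sum(axis=(1, 2))
        proto = self.counts[:, s, :, 1].sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, proto / np.maximum(tot, 1e-300), 0.0)

    def copy(self) -> "PopulationState":
        return PopulationState(self.counts.copy(), self.pools.copy())


def initial_state(culture_type: str, n_replicates: int,
                  params: SimParams) -> PopulationState:
    """Inoculate fresh medium the way the evolution experiment starts.

    Monocultures: 40 µl of an OD-0.1 preculture into 960 µl (4e6 cells/ml).
    Cocultures: 20 µl of each strain's preculture (2e6 cells/ml per strain),
    plus a small amino-acid carryover pool from the preculture supernatant.
    """
    L = params.n_levels
    counts = np.zeros((n_replicates, 2, L + 1, 2))
    preculture = params.inoculum_od / params.od_per_1e9 * 1e9  # cells/ml
    pools = np.zeros((n_replicates, 2))
    if culture_type == "CO":
        counts[:, 0, 0, 0] = preculture * 0.02
        counts[:, 1, 0, 0] = preculture * 0.02
        pools[:] = params.init_pool_co
    elif culture_type == "TRP_mono":
        counts[:, 0, 0, 0] = preculture * 0.04
    elif culture_type == "TYR_mono":
        counts[:, 1, 0, 0] = preculture * 0.04
    else:
        raise ValueError(f"unknown culture type {culture_type!r}")
    return PopulationState(counts, pools)


def _mutation_draw(mean: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    if rng is None:
        return mean
    return rng.poisson(mean).astype(float)


def run_batch(state: PopulationState, params: SimParams, conc: float,
              antibiotic: str = "NONE", *, supplemented: bool = False,
              supplement_conc: float = 100.0,
              rng: np.random.Generator | None = None,
              record_times: tuple[float, ...] | None = None):
    """Integrate one 72-h growth batch; return (new state, OD600 readout).

    With ``rng=None`` the batch is fully deterministic (no OD noise,
    mutation flows at expectation). ``record_times`` optionally returns
    total cell counts per strain on a time grid (hours), as a third element
    of the returned tuple.
    """
    if conc < 0:
        raise ValueError("antibiotic concentration must be non-negative")
    st = state.copy()
    counts, pools = st.counts, st.pools
    R, _, Lp1, _ = counts.shape

    if supplemented:
        pools += supplement_conc

    levels = np.arange(Lp1)
    mic = params.mic0[antibiotic] * params.mic_multiplier ** levels
    with np.errstate(over="ignore", divide="ignore"):
        x_k = np.where(np.isfinite(mic), (conc / mic) ** params.kappa, 0.0)
    g_ab = 1.0 / (1.0 + x_k)                       # (L+1,)
    kill = params.delta_max * x_k / (1.0 + x_k)    # (L+1,)
    bactericidal = params.mode.get(antibiotic, "bacteriostatic") == "bactericidal"
    r = np.array([params.growth_rate["TRP"], params.growth_rate["TYR"]])

    def rates(c: np.ndarray, p: np.ndarray):
        """Instantaneous growth, kill, and pool rates at state (c, p)."""
        n_tot = c.sum(axis=(1, 2, 3))
        crowd = np.clip(1.0 - n_tot / params.capacity, 0.0, None)
        monod = p / (params.k_aa + p)          # (R, 2): pool s limits strain s
        g_aa = np.empty((R, 2, 1, 2))
        g_aa[:, :, 0, 0] = monod
        g_aa[:, :, 0, 1] = 1.0
        mu = (r[None, :, None, None] * g_aa * g_ab[None, None, :, None]
              * crowd[:, None, None, None])
        grow = mu * c                          # new cells per hour, per class
        cons = 1000.0 * params.consumption * grow[:, :, :, 0].sum(axis=2) / 1e9
        prod = 1000.0 * params.production * grow.sum(axis=(2, 3)) / 1e9
        dc = grow.copy()
        if bactericidal:
            dc -= kill[None, None, :, None] * c
        # strain 0 (TRP) releases Tyr (pool 1); strain 1 releases Trp (pool 0)
        dp = prod[:, ::-1] - cons
        return dc, dp, grow

    dt = params.dt
    n_steps = int(round(params.batch_hours / dt))
    recorded = {}
    if record_times is not None:
        step_of = {int(round(t / dt)): float(t) for t in record_times}
        if 0 in step_of:
            recorded[0.0] = counts.sum(axis=(2, 3)).copy()

    for step in range(1, n_steps + 1):
        # Heun (second-order) step for the continuous dynamics
        dc1, dp1, g1 = rates(counts, pools)
        c_mid = np.clip(counts + dt * dc1, 0.0, None)
        p_mid = np.clip(pools + dt * dp1, 0.0, None)
        dc2, dp2, g2 = rates(c_mid, p_mid)
        d_new = 0.5 * dt * (g1 + g2)               # new cells this step
        counts += 0.5 * dt * (dc1 + dc2)
        pools += 0.5 * dt * (dp1 + dp2)
        np.clip(counts, 0.0, None, out=counts)
        np.clip(pools, 0.0, None, out=pools)

        if params.mu_res > 0:
            m = _mutation_draw(d_new[:, :, :-1, :] * params.mu_res, rng)
            m = np.minimum(m, counts[:, :, :-1, :])
            counts[:, :, :-1, :] -= m
            counts[:, :, 1:, :] += m
        if params.mu_rev > 0:
            m = _mutation_draw(np.clip(d_new[:, :, :, 0], 0.0, None)
                               * params.mu_rev, rng)
            m = np.minimum(m, counts[:, :, :, 0])
            counts[:, :, :, 0] -= m
            counts[:, :, :, 1] += m

        if not np.all(np.isfinite(counts)) or not np.all(np.isfinite(pools)):
            raise IntegrationError(
                f"non-finite state at step {step} (t = {step * dt:.2f} h)")

        if record_times is not None and step in step_of:
            recorded[step_of[step]] = counts.sum(axis=(2, 3)).copy()

    od = params.od_per_1e9 * counts.sum(axis=(1, 2, 3)) / 1e9
    if rng is not None and params.od_noise > 0:
        od = od * np.exp(rng.normal(0.0, params.od_noise, size=R))
    if record_times is not None:
        return st, od, recorded
    return st, od


def run_experiment(design: ExperimentDesign,
                   ramps: Mapping[str, RampSchedule],
                   params: SimParams | None = None,
                   cfg: RunConfig | None = None,
                   seed: int = 0, *, deterministic: bool = False,
                   return_states: bool = False):
    """Simulate the whole serial-transfer experiment; return a transfers table.

    Every replicate is inoculated, carried through ``n_transfers + 1``
    72-h growth periods under its antibiotic's ramp schedule with a 1/25
    dilution between periods, and its end-of-batch OD600 recorded. A
    lineage whose OD falls below the death threshold is marked dead at that
    transfer and no longer propagated (no later rows).

    With ``return_states=True`` also returns a dict mapping
    ``(culture_type, antibiotic, replicate_id)`` to the final 72-h
    pre-dilution :class:`PopulationState` slice of each replicate (dead
    replicates hold zero counts).
    """
    params = params or SimParams.default()
    cfg = cfg or RunConfig()
    rows: list[dict] = []
    states: dict[tuple[str, str], PopulationState] = {}
    for (ct, ab), cell in design.table.groupby(["culture_type", "antibiotic"],
                                               sort=False):
        ramp = ramps[ab].conc_by_transfer
        if len(ramp) != cfg.n_transfers + 1:
            raise ValueError(
                f"ramp for {ab} has {len(ramp)} entries, design expects "
                f"{cfg.n_transfers + 1}")
        rng = None if deterministic else child_rng(seed, "run_experiment", ct, ab)
        ids = cell["replicate_id"].tolist()
        supplemented = bool(cell["supplemented"].iloc[0])
        state = initial_state(ct, len(ids), params)
        alive = np.ones(len(ids), dtype=bool)
        for t in range(cfg.n_transfers + 1):
            state, od = run_batch(
                state, params, ramp[t], ab, supplemented=supplemented,
                supplement_conc=cfg.supplement_conc, rng=rng)
            died = alive & (od < cfg.death_threshold)
            for i, rid in enumerate(ids):
                if not alive[i]:
                    continue
                rows.append({"lineage_id": rid, "culture_type": ct,
                             "antibiotic": ab, "transfer": t,
                             "od600": float(od[i]),
                             "concentration": float(ramp[t]),
                             "alive": not died[i]})
            alive &= ~died
            state.counts[~alive] = 0.0
            if t < cfg.n_transfers:
                state.counts *= cfg.dilution_factor
                state.pools *= cfg.dilution_factor
        states[(ct, ab)] = state
    table = pd.DataFrame(rows)
    if return_states:
        return table, states
    return table


def final_states(design: ExperimentDesign, ramps: Mapping[str, RampSchedule],
                 params: SimParams | None = None, cfg: RunConfig | None = None,
                 seed: int = 0, *, deterministic: bool = False
                 ) -> dict[tuple[str, str], PopulationState]:
    """End-of-experiment population states per (culture type, antibiotic).

    Convenience wrapper over :func:`run_experiment`: the 72-h pre-dilution
    state after the final transfer (dead replicates hold zero counts).
    """
    _, states = run_experiment(design, ramps, params, cfg, seed=seed,
                               deterministic=deterministic, return_states=True)
    return states


def gen_mic_assay(mic: float, params: SimParams | None = None,
                  grid: np.ndarray | None = None, n_replicates: int = 3,
                  seed: int = 0, *, strain: str = "TRP",
                  antibiotic: str = "KAN", culture_type: str = "TRP_mono",
                  deterministic: bool = False) -> pd.DataFrame:
    """Simulate a supplemented dose-response MIC plate for a strain of MIC *mic*.

    Returns an ``mic_plates`` table: OD600 after 72 h at each grid
    concentration, monotone non-increasing in expectation.
    """
    params = params or SimParams.default()
    if grid is None or len(grid) == 0:
        raise ValueError("a non-empty, increasing concentration grid is required")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("concentration grid must be strictly increasing")
    p = replace(params, mic0={**params.mic0, antibiotic: float(mic)},
                mu_res=0.0, mu_rev=0.0)
    rng = None if deterministic else child_rng(seed, "gen_mic_assay", antibiotic)
    rows = []
    for conc in grid:
        state = initial_state("TRP_mono" if strain == "TRP" else "TYR_mono",
                              n_replicates, p)
        _, od = run_batch(state, p, float(conc), antibiotic,
                          supplemented=True, rng=rng)
        for rep in range(n_replicates):
            rows.append({"replicate_id": f"rep{rep}", "culture_type": culture_type,
                         "supplemented": True, "concentration": float(conc),
                         "od600": float(od[rep])})
    df = pd.DataFrame(rows)
    return df.sort_values(["replicate_id", "concentration"]).reset_index(drop=True)


def gen_colony_screen(frequencies: Mapping[str, float], n_colonies: int,
                      seed: int = 0, *, population_id: str = "pop0",
                      total_cfu_per_ml: float = 1e9,
                      lower_detection: float = 2.5e4,
                      upper_detection: float = 2.5e6) -> pd.DataFrame:
    """Draw a colony screen from population genotype frequencies.

    Genotype keys: ``prototroph``, ``TRP_aux`` (requires tryptophan),
    ``TYR_aux`` (requires tyrosine). Genotypes whose population frequency
    falls below the lower detection limit (relative to ``total_cfu_per_ml``)
    yield zero expected detections. Each colony carries growth flags on the
    four selective media (MMAB, MMAB+Trp, MMAB+Tyr, LB).
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be at least 1")
    freqs = {k: float(v) for k, v in frequencies.items()}
    known = {"prototroph", "TRP_aux", "TYR_aux"}
    if set(freqs) - known:
        raise ValueError(f"unknown genotypes: {sorted(set(freqs) - known)}")
    total = sum(freqs.values())
    if total <= 0 or abs(total - 1.0) > 1e-6 or any(v < 0 for v in freqs.values()):
        raise ValueError("frequencies must be non-negative and sum to 1")
    floor = lower_detection / total_cfu_per_ml
    detectable = {k: (0.0 if v < floor else v) for k, v in freqs.items()}
    norm = sum(detectable.values())
    if norm == 0:
        raise ValueError("no genotype above the lower detection limit")
    names = sorted(detectable)
    probs = np.array([detectable[k] / norm for k in names])
    rng = child_rng(seed, "gen_colony_screen", population_id)
    draws = rng.multinomial(n_colonies, probs)
    flags = {
        "prototroph": (True, True, True, True),
        "TRP_aux": (False, True, False, True),   # grows only with Trp (and on LB)
        "TYR_aux": (False, False, True, True),
    }
    rows = []
    cid = 0
    for name, count in zip(names, draws):
        mmab, trp, tyr, lb = flags[name]
        for _ in range(count):
            rows.append({"population_id": population_id,
                         "colony_id": f"{population_id}:c{cid:04d}",
                         "mmab": mmab, "mmab_trp": trp,
                         "mmab_tyr": tyr, "lb": lb})
            cid += 1
    df = pd.DataFrame(rows).sample(frac=1.0, random_state=int(
        child_rng(seed, "screen_order", population_id).integers(2**31)))
    return df.reset_index(drop=True)


def screen_final_populations(states: Mapping[tuple, PopulationState],
                             strain: str = "TYR", n_colonies: int = 9,
                             seed: int = 0, *,
                             lower_detection: float = 2.5e4) -> pd.DataFrame:
    """Colony-screen every surviving replicate population of an experiment.

    For each (culture type, antibiotic) entry of *states* and each replicate
    whose focal strain sits above the plating detection limit, draws
    ``n_colonies`` colonies from the strain's prototroph/auxotroph
    frequencies (detection limits apply within the screen too) and returns
    one colonies table with ``population_id`` encoding the group as
    ``{culture_type}:{antibiotic}:rep{i}``. Strains below the detection
    limit cannot be isolated on plates and are skipped.
    """
    aux = f"{strain}_aux"
    frames = []
    for (ct, ab), state in states.items():
        totals = state.strain_total(strain)
        pf = state.prototroph_fraction(strain)
        for i in np.flatnonzero(totals >= lower_detection):
            freqs = {"prototroph": float(pf[i]), aux: float(1.0 - pf[i])}
            frames.append(gen_colony_screen(
                freqs, n_colonies, seed=seed,
                population_id=f"{ct}:{ab}:rep{i}",
                total_cfu_per_ml=float(totals[i]),
                lower_detection=lower_detection))
    if not frames:
        raise ValueError("no surviving populations to screen")
    return pd.concat(frames, ignore_index=True)


def gen_growth_curves(params: SimParams | None = None, *,
                      culture_type: str = "CO", supplemented: bool = False,
                      n_replicates: int = 3, seed: int = 0,
                      deterministic: bool = False,
                      drop_volume_ml: float = 0.015) -> pd.DataFrame:
    """Simulate drop-plating growth kinetics on the fixed time grid.

    CFU/ml per strain at each grid time; stochastic mode applies Poisson
    counting noise of the 15-µl drop at an automatically chosen dilution
    targeting high colony counts (~1000). The assay characterises ancestral
    growth kinetics over a single 72-h batch, a horizon on which mutation
    is irrelevant, so mutation flows are switched off.
    """
    params = replace(params or SimParams.default(), mu_res=0.0, mu_rev=0.0)
    rng = None if deterministic else child_rng(
        seed, "gen_growth_curves", culture_type, supplemented)
    state = initial_state(culture_type, n_replicates, params)
    _, _, recorded = run_batch(
        state, params, 0.0, "NONE", supplemented=supplemented,
        rng=rng, record_times=tuple(float(t) for t in TIME_GRID_H))
    strains = (["TRP", "TYR"] if culture_type == "CO"
               else ["TRP" if culture_type == "TRP_mono" else "TYR"])
    rows = []
    for t in TIME_GRID_H:
        per_strain = recorded[float(t)]
        for s in strains:
            col = per_strain[:, STRAIN_INDEX[s]]
            for rep in range(n_replicates):
                cfu = float(col[rep])
                if not deterministic and cfu > 0:
                    dil = max(0.0, np.floor(np.log10(
                        max(cfu * drop_volume_ml / 1000.0, 1.0))))
                    expected = cfu * drop_volume_ml / 10 ** dil
                    counted = rng.poisson(expected)
                    cfu = counted * 10 ** dil / drop_volume_ml
                rows.append({"replicate_id": f"{culture_type}:rep{rep}",
                             "strain": s, "time_h": float(t),
                             "cfu_per_ml": cfu})
    return pd.DataFrame(rows)
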