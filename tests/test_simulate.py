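import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from muevolab import io
from muevolab.config import TIME_GRID_H, RunConfig
from muevolab.design import build_design, build_ramp, default_ramps
from muevolab.growth import call_mic
from muevolab.simulate import (PopulationState, SimParams, gen_colony_screen,
                               gen_growth_curves, gen_mic_assay, initial_state,
                               run_batch, run_experiment)


def test_obligate_auxotroph_cannot_grow_unsupplemented(ecology_params):
    """Without partner or supplement, an auxotroph monoculture stays put."""
    state = initial_state("TRP_mono", 1, ecology_params)
    n0 = state.total()[0]
    out, od = run_batch(state, ecology_params, 0.0, "NONE", supplemented=False)
    assert out.total()[0] <= n0 * 1.001


def test_prototroph_matches_closed_form_logistic(ecology_params):
    """A prototroph at zero antibiotic follows the logistic growth law.

    Oracle: the exact closed-form logistic solution
    N(t) = C / (1 + (C/N0 - 1) exp(-r t)).
    """
    p = ecology_params
    state = initial_state("TRP_mono", 1, p)
    n0 = state.total()[0]
    state.counts[:] = 0.0
    state.counts[0, 0, 0, 1] = n0  # prototroph class: no amino-acid limit
    out, od = run_batch(state, p, 0.0, "NONE", supplemented=False)
    r = p.growth_rate["TRP"]
    expected = p.capacity / (1 + (p.capacity / n0 - 1) * np.exp(-r * p.batch_hours))
    assert out.total()[0] == pytest.approx(expected, rel=0.01)


def test_saturating_bacteriostatic_concentration_freezes_growth(ecology_params):
    state = initial_state("TRP_mono", 1, ecology_params)
    n0 = state.total()[0]
    out, od = run_batch(state, ecology_params, 1e9, "TET", supplemented=True)
    assert out.total()[0] == pytest.approx(n0, rel=1e-6)


def test_bacteriostatic_dose_response_is_monotone(ecology_params):
    """Deterministic final density never increases with concentration."""
    finals = []
    for conc in [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0]:
        state = initial_state("TRP_mono", 1, ecology_params)
        out, _ = run_batch(state, ecology_params, conc, "TET", supplemented=True)
        finals.append(out.total()[0])
    assert np.all(np.diff(finals) <= 1e-6 * finals[0])


def test_amino_acid_mass_balance(ecology_params):
    """Pool change equals supplement minus growth-coupled consumption.

    With production routed to the partner pool, the tryptophan pool of a
    supplemented TRP monoculture must close its budget exactly: every 1e9
    new auxotroph cells consume `consumption` µmol (= 100 µM here).
    """
    p = ecology_params
    state = initial_state("TRP_mono", 1, p)
    n0 = state.total()[0]
    out, _ = run_batch(state, p, 0.0, "NONE", supplemented=True,
                       supplement_conc=100.0)
    grown = out.total()[0] - n0
    consumed = 1000.0 * p.consumption * grown / 1e9
    assert out.pools[0, 0] == pytest.approx(100.0 - consumed, abs=1e-6)
    assert np.all(out.pools >= 0)


def test_halving_time_step_changes_little(ecology_params):
    p_coarse = replace(ecology_params, dt=0.2)
    p_fine = replace(ecology_params, dt=0.1)
    for ct, supp in [("TRP_mono", True), ("CO", False)]:
        a, _ = run_batch(initial_state(ct, 1, p_coarse), p_coarse, 0.0, "NONE",
                         supplemented=supp)
        b, _ = run_batch(initial_state(ct, 1, p_fine), p_fine, 0.0, "NONE",
                         supplemented=supp)
        assert a.total()[0] == pytest.approx(b.total()[0], rel=5e-3)


def test_negative_state_rejected():
    with pytest.raises(ValueError):
        PopulationState(counts=-np.ones((1, 2, 9, 2)), pools=np.zeros((1, 2)))


class TestRunExperiment:
    def test_zero_antibiotic_everyone_survives(self, ecology_params):
        cfg = RunConfig(n_lineages=2, n_technical=1)
        design = build_design(cfg, antibiotics=("KAN",))
        none_ramp = replace(default_ramps(cfg)["KAN"],
                            conc_by_transfer=(0.0,) * (cfg.n_transfers + 1))
        table = run_experiment(design, {"KAN": none_ramp}, ecology_params, cfg,
                               deterministic=True)
        last = table.groupby("lineage_id").tail(1)
        assert (last["transfer"] == cfg.n_transfers).all()
        assert last["alive"].all()

    def test_dead_lineage_has_no_later_records(self, ecology_params):
        # a lethal bactericidal jolt from transfer 2 kills everything
        cfg = RunConfig(n_lineages=2, n_technical=1)
        design = build_design(cfg, culture_types=("CO",), antibiotics=("KAN",))
        hot = (0.0, 0.0) + (1e4,) * (cfg.n_transfers - 1)
        ramp = replace(default_ramps(cfg)["KAN"], conc_by_transfer=hot)
        table = run_experiment(design, {"KAN": ramp}, ecology_params, cfg,
                               deterministic=True)
        for _, sub in table.groupby("lineage_id"):
            sub = sub.sort_values("transfer")
            assert not sub["alive"].iloc[-1]
            assert sub["alive"].iloc[:-1].all()
            assert sub["transfer"].iloc[-1] <= 3

    def test_output_is_schema_valid_and_concentrations_match_ramp(self, params):
        cfg = RunConfig(n_lineages=2, n_technical=1)
        design = build_design(cfg, culture_types=("TRP_mono",),
                              antibiotics=("TET",))
        ramps = default_ramps(cfg)
        table = run_experiment(design, ramps, params, cfg, seed=7)
        validated = io.validate_table(table, "transfers")
        conc = validated.set_index("transfer")["concentration"]
        for t, c in conc.items():
            assert c == pytest.approx(ramps["TET"].conc_by_transfer[t])

    def test_seed_reproducibility(self, params):
        cfg = RunConfig(n_lineages=1, n_technical=2)
        design = build_design(cfg, culture_types=("CO",), antibiotics=("KAN",))
        ramps = default_ramps(cfg)
        a = run_experiment(design, ramps, params, cfg, seed=3)
        b = run_experiment(design, ramps, params, cfg, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestMICAssay:
    def test_extremes(self, params):
        grid = np.array([0.01, 1.0, 250.0])
        plate = gen_mic_assay(2.5, params, grid=grid, n_replicates=2,
                              deterministic=True)
        od = plate.groupby("concentration")["od600"].mean()
        assert od.iloc[0] > 0.5            # no antibiotic: near carrying capacity
        assert od.loc[250.0] < 0.01        # 100x the cell MIC: no growth

    def test_planted_mic_recovered_against_closed_form(self):
        """call_mic on a noise-free plate matches the logistic threshold crossing.

        With the Monod term saturated and no mutation, 72-h density is the
        closed-form logistic with rate r / (1 + (c/m)^kappa); the expected
        MIC call is the first grid point whose density is below OD 0.01.
        """
        p = replace(SimParams.default(), k_aa=1e-9, mu_res=0.0, mu_rev=0.0,
                    production=0.0, consumption=0.0)
        m, r = 2.5, p.growth_rate["TRP"]
        grid = np.round(np.geomspace(0.05, 40.0, 16), 4)
        n0 = p.inoculum_od / p.od_per_1e9 * 1e9 * 0.04
        g = 1.0 / (1.0 + (grid / m) ** p.kappa)
        n72 = p.capacity / (1 + (p.capacity / n0 - 1) * np.exp(-r * g * 72.0))
        od72 = p.od_per_1e9 * n72 / 1e9
        expected = grid[np.argmax(od72 < 0.01)]
        plate = gen_mic_assay(m, p, grid=grid, n_replicates=1, antibiotic="TET",
                              deterministic=True)
        called = call_mic(plate)
        assert called["mic"].iloc[0] == pytest.approx(expected)

    def test_empty_grid_rejected(self, params):
        with pytest.raises(ValueError):
            gen_mic_assay(2.5, params, grid=np.array([]))


class TestColonyScreen:
    def test_pure_auxotroph_flags(self):
        screen = gen_colony_screen({"TRP_aux": 1.0}, 20, seed=0)
        assert (~screen["mmab"]).all() and screen["mmab_trp"].all()
        assert (~screen["mmab_tyr"]).all() and screen["lb"].all()

    def test_pure_prototroph_flags(self):
        screen = gen_colony_screen({"prototroph": 1.0}, 20, seed=0)
        assert screen[["mmab", "mmab_trp", "mmab_tyr", "lb"]].all().all()

    def test_mixture_within_binomial_interval(self):
        """Revertant draw fraction stays inside the 99% binomial interval."""
        n = 1000
        screen = gen_colony_screen({"prototroph": 0.3, "TYR_aux": 0.7}, n, seed=11)
        k = int(screen["mmab"].sum())
        sd = np.sqrt(0.3 * 0.7 / n)
        assert abs(k / n - 0.3) < 2.576 * sd

    def test_below_detection_limit_never_sampled(self):
        screen = gen_colony_screen({"prototroph": 1e-6, "TYR_aux": 1 - 1e-6},
                                   5000, seed=2, total_cfu_per_ml=1e9,
                                   lower_detection=2.5e4)
        assert not screen["mmab"].any()  # 1e-6 < 2.5e4/1e9 frequency floor

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            gen_colony_screen({"prototroph": 0.5, "TYR_aux": 0.2}, 10)


class TestGrowthCurves:
    def test_time_zero_equals_inoculum(self, ecology_params):
        df = gen_growth_curves(ecology_params, culture_type="TRP_mono",
                               supplemented=True, n_replicates=1,
                               deterministic=True)
        t0 = df[df.time_h == 0]["cfu_per_ml"].iloc[0]
        assert t0 == pytest.approx(0.1 * 1e9 * 0.04)

    def test_counting_noise_is_small_at_high_density(self, ecology_params):
        reps = [gen_growth_curves(ecology_params, culture_type="TRP_mono",
                                  supplemented=True, n_replicates=1, seed=s)
                for s in range(12)]
        finals = np.array([r[r.time_h == 72]["cfu_per_ml"].iloc[0] for r in reps])
        assert finals.std() / finals.mean() < 0.05

    def test_schema_valid(self, ecology_params):
        df = gen_growth_curves(ecology_params, culture_type="CO",
                               supplemented=False, n_replicates=2, seed=1)
        io.validate_table(df, "growth_curves")
        assert set(df["strain"]) == {"TRP", "TYR"}
        assert len(df) == 2 * 2 * len(TIME_GRID_H)
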