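"""The synthetic-data generator: determinism, zero-noise collapse, structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from befthermal import SimulationConfig, generate_species_pool
from befthermal.simulate import (
    default_design, monoculture_capacity, simulate_bef_response,
    simulate_community_experiment, simulate_cytometry_events,
    simulate_pi_assays, simulate_tpc_assay,
)
from befthermal.thermal import sharpe_schoolfield_ln_rate
from befthermal.traits import substream


class TestSpeciesPool:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=1)
        assert generate_species_pool(cfg) == generate_species_pool(cfg)

    def test_different_seeds_differ(self):
        a = generate_species_pool(SimulationConfig(seed=1))
        b = generate_species_pool(SimulationConfig(seed=2))
        assert a != b

    def test_topt_spread_within_requested_range(self):
        cfg = SimulationConfig(seed=3, topt_range=(18.0, 36.0))
        pool = generate_species_pool(cfg)
        assert len(pool) == 16
        spread = (max(s.topt_true_C for s in pool)
                  - min(s.topt_true_C for s in pool))
        assert 0 < spread <= 18.0 + 1e-9

    def test_unimodality_invariant_holds_for_all_records(self, pool):
        for sp in pool:
            assert sp.Eh > sp.E > 0
            assert sp.topt_true < sp.Th

    def test_invalid_topt_range_rejected(self):
        with pytest.raises(ValueError, match="topt_range"):
            SimulationConfig(topt_range=(30.0, 20.0))

    def test_cluster_centres_separated(self, pool, config):
        c = np.array([[s.fsc_mu, s.ssc_mu, s.fl3_mu] for s in pool])
        d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= config.min_cluster_separation - 1e-9


class TestTPCAssay:
    def test_zero_noise_equals_closed_form(self, pool):
        cfg = dataclasses.replace(SimulationConfig(seed=1), noise_sd_rate=0.0)
        sp = pool[4]
        tab = simulate_tpc_assay(sp, cfg)
        expected = np.exp(sharpe_schoolfield_ln_rate(
            tab["assay_temp_C"].to_numpy(), sp.lnb_tc, sp.E, sp.Eh, sp.Th
        ))
        np.testing.assert_allclose(tab["gp_rate"].to_numpy(), expected)

    def test_zero_noise_argmax_near_true_optimum(self, pool):
        sp = pool[7]
        cfg = dataclasses.replace(
            SimulationConfig(seed=1), noise_sd_rate=0.0,
            assay_temperatures=tuple(np.arange(7.0, 49.0, 0.05)),
        )
        tab = simulate_tpc_assay(sp, cfg)
        argmax = tab.loc[tab["gp_rate"].idxmax(), "assay_temp_C"]
        assert abs(argmax - sp.topt_true_C) <= 0.05

    def test_noise_mean_converges_to_expectation(self, pool):
        # lognormal noise: E[rate] = curve * exp(sd^2/2)
        sp = pool[0]
        cfg = dataclasses.replace(
            SimulationConfig(seed=1), assay_temperatures=(20.0,)
        )
        rng = substream(99, "mc")
        draws = np.array([
            simulate_tpc_assay(sp, cfg, rng=rng)["gp_rate"].iloc[0]
            for _ in range(500)
        ])
        mu = np.exp(sharpe_schoolfield_ln_rate(20.0, sp.lnb_tc, sp.E, sp.Eh,
                                               sp.Th))
        expected = mu * np.exp(cfg.noise_sd_rate ** 2 / 2)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se
        assert (draws > 0).all()

    def test_pi_assay_table_schema(self, pool, config):
        rates = simulate_pi_assays(pool[:2], config)
        assert set(rates.columns) == {
            "species_id", "assay_temp_C", "irradiance_umol_m2_s", "o2_rate",
            "cell_density_per_mL",
        }
        dark = rates[rates["irradiance_umol_m2_s"] == 0]
        assert (dark["o2_rate"] < 0).all()     # respiration consumes O2


class TestCommunityExperiment:
    def test_determinism(self, pool, design, config):
        a = simulate_community_experiment(pool, design, config)
        b = simulate_community_experiment(pool, design, config)
        pd.testing.assert_frame_equal(a.units, b.units)
        pd.testing.assert_frame_equal(a.species_abundances,
                                      b.species_abundances)

    def test_pool_mismatch_rejected(self, pool, design, config):
        with pytest.raises(ValueError, match="not in pool"):
            simulate_community_experiment(pool[:8], design, config)

    def test_noise_free_monoculture_equals_capacity(self, pool, design):
        cfg = dataclasses.replace(SimulationConfig(seed=11), well_noise_sd=0.0)
        expt = simulate_community_experiment(pool, design, cfg)
        monos = expt.units[expt.units["richness"] == 1]
        by_id = {sp.species_id: sp for sp in pool}
        for row in monos.itertuples(index=False):
            cap = monoculture_capacity(by_id[row.species], row.temperature_C,
                                       cfg)
            assert row.total_chl == pytest.approx(cap, rel=1e-9)

    def test_best_species_at_30C_has_highest_monoculture(self, pool, design):
        cfg = dataclasses.replace(SimulationConfig(seed=11), well_noise_sd=0.0)
        expt = simulate_community_experiment(pool, design, cfg)
        monos = expt.units[(expt.units["richness"] == 1)
                           & (expt.units["temperature_C"] == 30.0)]
        mono_mean = monos.groupby("species")["total_chl"].mean()
        caps = {sp.species_id: monoculture_capacity(sp, 30.0, cfg)
                for sp in pool}
        assert mono_mean.idxmax() == max(caps, key=caps.get)

    def test_abundances_nonnegative_and_consistent(self, experiment):
        ab = experiment.species_abundances
        assert (ab["abundance"] >= 0).all()
        totals = ab.groupby("unit_id")["abundance"].sum()
        units = experiment.units.set_index("unit_id")["abundance"]
        np.testing.assert_allclose(totals[units.index], units, rtol=1e-9)


class TestCytometrySimulation:
    def test_all_zero_abundance_no_debris_is_empty(self, pool):
        cfg = dataclasses.replace(SimulationConfig(seed=1), debris_fraction=0.0)
        ev = simulate_cytometry_events({sp.species_id: 0.0 for sp in pool},
                                       pool, 20.0, cfg)
        assert len(ev) == 0

    def test_poisson_event_count(self, pool):
        # 1000 cells/mL in 20 uL -> mean 20 events
        cfg = dataclasses.replace(SimulationConfig(seed=1), debris_fraction=0.0)
        rng = substream(7, "poisson")
        counts = [
            len(simulate_cytometry_events({pool[0].species_id: 1000.0}, pool,
                                          20.0, cfg, rng=rng))
            for _ in range(200)
        ]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 20.0) < 3 * se

    def test_negative_abundance_rejected(self, pool, config):
        with pytest.raises(ValueError, match="negative abundance"):
            simulate_cytometry_events({pool[0].species_id: -5.0}, pool, 20.0,
                                      config)

    def test_debris_below_thresholds(self, pool, config):
        from befthermal.cytometry import filter_events

        ev = simulate_cytometry_events({pool[0].species_id: 5e4}, pool, 20.0,
                                       config)
        debris = ev[ev["species_id"] == "debris"]
        assert len(debris) > 0
        assert filter_events(debris).n_kept == 0


class TestBEFResponseGenerator:
    def test_linear_truth_recovered_without_noise(self, design):
        out = simulate_bef_response(
            design, intercepts={15.0: 5, 25.0: 4, 30.0: 3},
            slopes={15.0: 1.0, 25.0: 1.5, 30.0: 2.0}, noise_sd=0.0,
        )
        r16 = out[(out["richness"] == 16) & (out["temperature_C"] == 30.0)]
        assert np.allclose(r16["ln_chl"], 3 + 2.0 * 4)

    def test_species_effects_added_when_present(self, design):
        out = simulate_bef_response(
            design, noise_sd=0.0, species_effects={"sp01": 2.0},
            intercepts={t: 0.0 for t in (15.0, 25.0, 30.0)},
            slopes={t: 0.0 for t in (15.0, 25.0, 30.0)},
        )
        has = out["species"].str.contains("sp01")
        assert np.allclose(out.loc[has, "ln_chl"], 2.0)
        assert np.allclose(out.loc[~has, "ln_chl"], 0.0)
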