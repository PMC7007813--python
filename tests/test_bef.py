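"""The BEF statistical engine: sequential models, contrasts, coefficients."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from befthermal import SimulationConfig, simulate_bef_response
from befthermal.bef import (
    BEFModel, gaussian_aic, linear_regression, mono_poly_regression,
    overyielding, sequential_model_selection, slope_contrasts,
    species_coefficients, trait_correlation,
)
from befthermal.design import DesignTable, generate_full_design
from befthermal.simulate import (
    default_design, simulate_community_experiment,
)


@pytest.fixture(scope="module")
def null_data(design):
    return simulate_bef_response(
        design, slopes={15.0: 1.5, 25.0: 1.5, 30.0: 1.5},
        rng=np.random.default_rng(17),
    )


class TestSequentialModelTable:
    def test_residual_df_sequence_independent_of_response(self, design, rng):
        frame = design.frame.copy()
        frame["ln_chl"] = rng.standard_normal(len(frame))
        tbl = sequential_model_selection(frame)
        assert tbl["res_df"].tolist() == [1394, 1392, 1391, 1389]

    def test_table_arithmetic_invariants(self, null_data):
        tbl = sequential_model_selection(null_data)
        d_df = -np.diff(tbl["res_df"].to_numpy())
        assert np.allclose(d_df, tbl["treat_df"].to_numpy()[1:])
        d_ss = -np.diff(tbl["res_ss"].to_numpy())
        assert np.allclose(d_ss, tbl["treat_ss"].to_numpy()[1:])
        tss = tbl["res_ss"].iloc[0]
        assert np.allclose(tbl["r_squared"], 1 - tbl["res_ss"] / tss)
        assert (np.diff(tbl["res_ss"]) <= 1e-9).all()
        assert (np.diff(tbl["r_squared"]) >= -1e-12).all()

    def test_aic_matches_closed_form_delta(self, null_data):
        tbl = sequential_model_selection(null_data)
        n = len(null_data)
        for i in (1, 2, 3):
            d_aic = tbl["aic"].iloc[i] - tbl["aic"].iloc[i - 1]
            rss_big, rss_small = tbl["res_ss"].iloc[i - 1], tbl["res_ss"].iloc[i]
            d_k = tbl["res_df"].iloc[i - 1] - tbl["res_df"].iloc[i]
            expected = -n * np.log(rss_big / rss_small) + 2 * d_k
            assert d_aic == pytest.approx(expected, abs=1e-8)

    def test_f_statistics_match_statsmodels_anova(self):
        # independent oracle: sequential (type-I) ANOVA on a small table
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        toy = pd.DataFrame({
            "temperature_C": np.repeat([15.0, 25.0, 30.0], 4),
            "richness": list([1, 2, 4, 8]) * 3,
        })
        toy["ln_chl"] = rng.standard_normal(12)
        toy["log2R"] = np.log2(toy["richness"])
        tbl = sequential_model_selection(toy)
        fit = smf.ols("ln_chl ~ C(temperature_C) * log2R", toy).fit()
        anova = sm.stats.anova_lm(fit, typ=1)
        # statsmodels tests every term against the FULL model's MSE; the
        # sequential table tests against the current step's MSE, so compare
        # treatment SS (identical) and the final-step F (identical scale).
        assert tbl["treat_ss"].iloc[1] == pytest.approx(
            anova.loc["C(temperature_C)", "sum_sq"])
        assert tbl["treat_ss"].iloc[2] == pytest.approx(
            anova.loc["log2R", "sum_sq"])
        assert tbl["treat_ss"].iloc[3] == pytest.approx(
            anova.loc["C(temperature_C):log2R", "sum_sq"])
        assert tbl["F"].iloc[3] == pytest.approx(
            anova.loc["C(temperature_C):log2R", "F"])

    def test_aic_matches_statsmodels(self, null_data):
        import statsmodels.formula.api as smf

        tbl = sequential_model_selection(null_data)
        null_data = null_data.assign(log2R=np.log2(null_data["richness"]))
        fit = smf.ols("ln_chl ~ C(temperature_C) * log2R", null_data).fit()
        # statsmodels does not count the error variance as a parameter;
        # the R-style convention used here adds exactly 2 to its AIC
        assert tbl["aic"].iloc[3] == pytest.approx(fit.aic + 2.0, rel=1e-9)

    def test_single_temperature_rejected(self, design, rng):
        frame = design.frame[design.frame["temperature_C"] == 15.0].copy()
        frame["ln_chl"] = rng.standard_normal(len(frame))
        with pytest.raises(ValueError, match="temperature"):
            sequential_model_selection(frame)

    def test_gaussian_aic_convention(self):
        # n ln(RSS/n) + 2(k+1) + n(ln 2pi + 1), the mainstream convention
        assert gaussian_aic(np.e * 10, 10, 1) == pytest.approx(
            10 * 1 + 2 * 2 + 10 * (np.log(2 * np.pi) + 1))


class TestSlopeContrasts:
    def test_slopes_match_statsmodels(self, null_data):
        import statsmodels.formula.api as smf

        sc = slope_contrasts(null_data)
        data = null_data.assign(log2R=np.log2(null_data["richness"]))
        fit = smf.ols("ln_chl ~ C(temperature_C) * log2R", data).fit()
        base = fit.params["log2R"]
        expected = {
            15.0: base,
            25.0: base + fit.params["C(temperature_C)[T.25.0]:log2R"],
            30.0: base + fit.params["C(temperature_C)[T.30.0]:log2R"],
        }
        got = sc.slopes.set_index("temperature_C")["slope"]
        for t, v in expected.items():
            assert got[t] == pytest.approx(v)

    def test_two_temperature_tukey_equals_t_test(self, design, rng):
        frame = design.frame[design.frame["temperature_C"] != 25.0].copy()
        frame["ln_chl"] = rng.standard_normal(len(frame))
        sc = slope_contrasts(frame)
        from scipy import stats

        t = abs(sc.contrasts["t"].iloc[0])
        p_t = 2 * stats.t.sf(t, sc.df_resid)
        assert sc.contrasts["p_tukey"].iloc[0] == pytest.approx(p_t, rel=1e-6)

    def test_doubled_slope_detected(self, design):
        data = simulate_bef_response(design, rng=np.random.default_rng(5))
        sc = slope_contrasts(data)
        row = sc.contrasts.set_index("contrast").loc["30 - 15"]
        assert row["estimate"] > 0
        assert row["p_tukey"] < 0.05

    def test_single_temperature_rejected(self, design, rng):
        frame = design.frame[design.frame["temperature_C"] == 15.0].copy()
        frame["ln_chl"] = rng.standard_normal(len(frame))
        with pytest.raises(ValueError, match=">= 2 temperature"):
            slope_contrasts(frame)


class TestSpeciesCoefficients:
    def _sub(self, design, temperature=30.0):
        frame = design.frame
        sub = frame[frame["temperature_C"] == temperature].reset_index(
            drop=True)
        return sub, DesignTable(sub).presence_matrix()

    def test_coefficients_sum_to_zero(self, design, rng):
        sub, presence = self._sub(design)
        sub = sub.assign(ln_chl=rng.standard_normal(len(sub)))
        cf = species_coefficients(sub, presence)
        assert cf["coefficient"].sum() == pytest.approx(0.0, abs=1e-10)

    def test_constructed_species_ranked_top(self, design):
        sub, presence = self._sub(design)
        rng = np.random.default_rng(2)
        target = presence.columns[3]
        y = 5.0 + 0.5 * np.log2(sub["richness"]) \
            + 1.0 * presence[target].to_numpy() \
            + 0.5 * rng.standard_normal(len(sub))
        cf = species_coefficients(sub.assign(ln_chl=y), presence)
        cf = cf.set_index("species_id")
        assert cf["coefficient"].idxmax() == target
        assert cf["coefficient"].drop(target).mean() < 0

    def test_null_coefficients_small(self, design):
        sub, presence = self._sub(design)
        rng = np.random.default_rng(4)
        y = 5.0 + 0.5 * np.log2(sub["richness"]) \
            + 0.1 * rng.standard_normal(len(sub))
        cf = species_coefficients(sub.assign(ln_chl=y), presence)
        assert cf["coefficient"].abs().max() < 0.15

    def test_absent_species_flagged(self, design, rng):
        sub, presence = self._sub(design)
        presence = presence.assign(ghost=0)
        sub = sub.assign(ln_chl=rng.standard_normal(len(sub)))
        cf = species_coefficients(sub, presence).set_index("species_id")
        assert bool(cf.loc["ghost", "flagged_absent"])
        assert np.isnan(cf.loc["ghost", "coefficient"])
        assert cf.loc[cf.index != "ghost", "coefficient"].sum() \
            == pytest.approx(0.0, abs=1e-10)


class TestSimpleRegressions:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        reg = trait_correlation(2 * x + 1, x)
        assert reg.r_squared == pytest.approx(1.0)
        assert reg.slope == pytest.approx(2.0)

    def test_permuted_traits_not_significant(self, rng):
        x = np.arange(16.0)
        y = 2 * x + rng.standard_normal(16)
        perm = rng.permutation(x)
        assert trait_correlation(y, perm).p > 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            linear_regression([1.0, 2.0], [1.0, 2.0])


class TestMonoPolyRegression:
    def test_identity_relation(self, experiment):
        # feed monoculture abundances as 'polyculture' shares too
        units = experiment.units
        ab = experiment.species_abundances
        reg = mono_poly_regression(ab, units, 25.0)
        assert reg.n >= 16

    def test_constructed_identity_slope(self):
        design = generate_full_design(
            [f"s{i}" for i in range(4)], levels=(1, 4), n_partitions=2,
            n_replicates=1, temperatures=(20.0,), seed=0)
        vals = {f"s{i}": float(10 + i) for i in range(4)}
        rows = []
        for row in design.frame.itertuples(index=False):
            for sp in row.species.split(";"):
                rows.append({"unit_id": row.unit_id, "species_id": sp,
                             "abundance": vals[sp]})
        reg = mono_poly_regression(pd.DataFrame(rows), design.frame, 20.0)
        assert reg.slope == pytest.approx(1.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_no_units_at_missing_temperature(self, experiment):
        with pytest.raises(ValueError, match="no units"):
            mono_poly_regression(experiment.species_abundances,
                                 experiment.units, 99.0)


class TestOveryielding:
    def test_all_identical_production_gives_zero(self, design):
        frame = design.frame.copy()
        frame["ln_chl"] = 5.0
        oy = overyielding(frame, 15.0, n_boot=50)
        assert oy.net_oy == pytest.approx(0.0)
        assert oy.trans_oy == pytest.approx(0.0)

    def test_poly_equal_to_best_mono(self, design, rng):
        frame = design.frame.copy()
        # species s: mono mean = rank; polyculture mean = best mono mean
        frame["ln_chl"] = 0.0
        monos = frame["richness"] == 1
        ranks = {sp: float(i) for i, sp in
                 enumerate(sorted(frame.loc[monos, "species"].unique()))}
        frame.loc[monos, "ln_chl"] = frame.loc[monos, "species"].map(ranks)
        frame.loc[frame["richness"] == 16, "ln_chl"] = max(ranks.values())
        oy = overyielding(frame, 15.0, n_boot=50)
        assert oy.trans_oy == pytest.approx(0.0)
        assert oy.net_oy > 0

    def test_pure_selection_effect_net_but_not_transgressive(self, pool,
                                                             design):
        cfg = dataclasses.replace(SimulationConfig(seed=11),
                                  dominance_exponent=np.inf,
                                  well_noise_sd=0.0)
        expt = simulate_community_experiment(pool, design, cfg)
        oy = overyielding(expt.units, 25.0, n_boot=100,
                          rng=np.random.default_rng(1))
        assert oy.net_oy > 0
        assert oy.trans_oy <= 1e-9

    def test_missing_monocultures_listed(self, design, rng):
        frame = design.frame.copy()
        frame["ln_chl"] = rng.standard_normal(len(frame))
        keep = ~((frame["richness"] == 1) & (frame["species"] == "sp01"))
        with pytest.raises(ValueError, match="sp01"):
            overyielding(frame[keep], 15.0, n_boot=10,
                         expected_species=[f"sp{i:02d}" for i in
                                           range(1, 17)])


class TestBEFModelObject:
    def test_fit_summary_and_best_model(self, experiment):
        res = BEFModel(experiment.units).fit()
        text = res.summary()
        assert "sequential linear models" in text
        assert "richness slopes" in text
        assert res.model_table["res_df"].tolist() == [1394, 1392, 1391, 1389]

    def test_missing_response_column_rejected(self, design):
        with pytest.raises(ValueError, match="ln_chl"):
            BEFModel(design.frame)
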