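"""Synthetic stream-site generator: determinism, calibration, recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from riparianpft import synthetic, traits
from riparianpft.synthetic import SimConfig, TABLE1_TARGETS


class TestDeterminism:
    def test_same_seed_identical_dataset(self):
        d1 = synthetic.generate_dataset(SimConfig(seed=1))
        d2 = synthetic.generate_dataset(SimConfig(seed=1))
        pd.testing.assert_frame_equal(d1.environment, d2.environment)
        pd.testing.assert_frame_equal(d1.responses, d2.responses)
        pd.testing.assert_frame_equal(d1.traits, d2.traits)

    def test_different_seed_differs(self):
        d1 = synthetic.generate_environment(SimConfig(seed=1))
        d2 = synthetic.generate_environment(SimConfig(seed=2))
        assert not d1.equals(d2)

    def test_truth_echoes_effect_matrix(self):
        cfg = SimConfig(seed=3)
        ds = synthetic.generate_dataset(cfg)
        assert ds.truth == cfg.effect_matrix
        assert ds.truth is not cfg.effect_matrix  # retained as a copy


class TestEnvironmentCalibration:
    def test_large_sample_matches_targets(self):
        env = synthetic.generate_environment(SimConfig(seed=0, n_sites=10_000))
        for var, t in TABLE1_TARGETS.items():
            col = env[var]
            assert abs(col.mean() - t.mean) <= 0.05 * abs(t.mean), var
            assert abs(col.std() - t.sd) <= 0.10 * t.sd, var
            assert col.min() >= t.min - 1e-9 and col.max() <= t.max + 1e-9, var

    def test_mean_annual_precipitation_example(self):
        env = synthetic.generate_environment(SimConfig(seed=0, n_sites=2000))
        assert env["PP"].mean() == pytest.approx(833, rel=0.05)

    def test_derived_columns_computed_not_sampled(self):
        env = synthetic.generate_environment(SimConfig(seed=4))
        np.testing.assert_allclose(env["PP_PET"], env["PP"] / env["PET"], rtol=1e-12)
        np.testing.assert_allclose(env["IDM"], env["PP"] / (env["Tmean"] + 10), rtol=1e-12)
        np.testing.assert_allclose(env["CN"], env["OC"] / env["N"], rtol=1e-12)

    def test_zero_coupling_decorrelates_soil(self):
        cfg = SimConfig(seed=5, n_sites=2000,
                        climate_soil_coupling={k: 0.0 for k in
                                               synthetic.DEFAULT_SOIL_COUPLING})
        env = synthetic.generate_environment(cfg)
        z = env.attrs["latent_aridity"]
        assert abs(np.corrcoef(z, env["EC"])[0, 1]) < 0.07
        # climate stays driven
        assert np.corrcoef(z, env["PP"])[0, 1] < -0.8

    def test_planted_collinearity(self):
        env = synthetic.generate_environment(SimConfig(seed=0, n_sites=2000))
        corr = env.corr()
        assert abs(corr.loc["PET", "PP_PET"]) > 0.85
        assert abs(corr.loc["IDM", "Q2"]) > 0.85

    def test_infeasible_bounds_rejected(self):
        bad = dict(TABLE1_TARGETS)
        bad["PP"] = synthetic.VariableTarget("climate", 833, 325, 1500, 1414)
        with pytest.raises(ValueError, match="PP"):
            synthetic.generate_environment(SimConfig(block_targets=bad))

    @pytest.mark.parametrize("field, value", [("n_sites", 5), ("noise_sd", 0.0)])
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            dataclasses.replace(SimConfig(), **{field: value}).validate()


class TestResponses:
    def test_null_effects_leave_no_association(self):
        eff = {k: {} for k in synthetic.DEFAULT_EFFECTS}
        rs = []
        for seed in range(50):
            cfg = SimConfig(seed=seed, effect_matrix=eff)
            env = synthetic.generate_environment(cfg)
            resp = synthetic.generate_pft_responses(env, cfg)
            rs.append(np.corrcoef(env["Tmean"], resp["cover_GG"])[0, 1])
        lo, hi = sps.t.interval(0.95, len(rs) - 1, loc=np.mean(rs),
                                scale=sps.sem(rs))
        assert lo < 0 < hi

    def test_strong_aridity_effect_recovered(self):
        eff = {k: {} for k in synthetic.DEFAULT_EFFECTS}
        eff["cover_GG"] = {"Tmean": 0.8}
        hits = 0
        for seed in range(100):
            cfg = SimConfig(seed=seed, effect_matrix=eff, noise_sd=0.3)
            env = synthetic.generate_environment(cfg)
            resp = synthetic.generate_pft_responses(env, cfg)
            rho = sps.spearmanr(env["Tmean"], resp["cover_GG"]).statistic
            hits += rho > 0
        assert hits >= 95

    def test_noiseless_limit_preserves_rank_order(self):
        eff = {k: {} for k in synthetic.DEFAULT_EFFECTS}
        eff["cover_GG"] = {"Tmean": 0.5}
        cfg = SimConfig(seed=6, effect_matrix=eff, noise_sd=1e-12,
                        cover_simplex=False)
        env = synthetic.generate_environment(cfg)
        resp = synthetic.generate_pft_responses(env, cfg)
        assert (env["Tmean"].rank().to_numpy()
                == resp["cover_GG"].rank().to_numpy()).all()

    def test_ranges_and_shapes(self, default_dataset):
        resp = default_dataset.responses
        assert list(resp.columns) == synthetic.RESPONSE_COLUMNS
        covers = resp[[c for c in resp.columns if c.startswith("cover")]]
        divs = resp[[c for c in resp.columns if c.startswith("div")]]
        assert ((covers >= 0) & (covers <= 100)).all().all()
        assert ((divs >= 0) & (divs < 1)).all().all()
        assert resp.index.equals(default_dataset.environment.index)

    def test_unknown_predictor_rejected(self):
        cfg = SimConfig(seed=0)
        env = synthetic.generate_environment(cfg)
        cfg.effect_matrix["cover_GG"] = {"no_such_var": 0.5}
        with pytest.raises(ValueError, match="no_such_var"):
            synthetic.generate_pft_responses(env, cfg)

    def test_diversity_increases_with_planted_predictor(self):
        eff = {k: {} for k in synthetic.DEFAULT_EFFECTS}
        eff["div_GG"] = {"Tmean": 1.5}
        rhos = []
        for seed in range(30):
            cfg = SimConfig(seed=seed, effect_matrix=eff, n_sites=60)
            env = synthetic.generate_environment(cfg)
            resp = synthetic.generate_pft_responses(env, cfg)
            rhos.append(sps.spearmanr(env["Tmean"], resp["div_GG"]).statistic)
        assert np.mean(rhos) > 0.3


class TestLeafTraits:
    def test_default_species_table(self, default_dataset):
        tr = default_dataset.traits
        assert tr.shape[0] == 32
        assert tr["pft"].value_counts().to_dict() == synthetic.DEFAULT_SPECIES_COUNTS
        assert (tr[traits.TRAIT_COLUMNS] > 0).all().all()

    @pytest.mark.parametrize("seed", range(10))
    def test_deciduous_evergreen_sla_ordering(self, seed):
        tr = synthetic.generate_leaf_traits(SimConfig(seed=seed))
        dec = tr[tr["pft"].isin(["DT", "DS"])]["SLA"].median()
        eve = tr[tr["pft"].isin(["ET", "ES"])]["SLA"].median()
        assert dec > eve
        tough_dec = tr[tr["pft"].isin(["DT", "DS"])]["toughness"].median()
        tough_eve = tr[tr["pft"].isin(["ET", "ES"])]["toughness"].median()
        assert tough_dec < tough_eve
        gg = tr[tr["pft"] == "GG"]
        other = tr[tr["pft"] != "GG"]
        assert gg["Si"].median() > 5 * other["Si"].median()
        assert gg["lignin"].median() < other["lignin"].median()

    def test_zero_separation_type_i_error_near_alpha(self):
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            tr = synthetic.generate_leaf_traits(
                SimConfig(seed=seed, trait_separation=0.0))
            groups = {g: np.log(sub["SLA"].to_numpy())
                      for g, sub in tr.groupby("pft")}
            res = traits.anova_oneway(groups)
            rejections += res.p < 0.05
        # binomial(200, 0.05): central 99% range is about [2, 20]
        assert 1 <= rejections <= 21
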