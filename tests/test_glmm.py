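"""Occupancy GLMM: linear predictor, Laplace fit, oracle equivalences,
symmetries and the two model variants."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from legrange import (
    OccupancyGLMM,
    continent_check,
    fit_both_variants,
    generate_world,
    linear_predictor,
)
from tests.conftest import moderate_config


class TestLinearPredictor:
    def test_all_zero_gives_half(self):
        S = np.ones((3, 1))
        P = linear_predictor([0.0], [], S, None)
        np.testing.assert_allclose(P, 0.5)

    def test_table_intercept_rate(self):
        S = np.ones((2, 1))
        P = linear_predictor([-8.055], [], S, None)
        np.testing.assert_allclose(P, expit(-8.055))
        assert P[0, 0] == pytest.approx(3.17e-4, rel=0.01)

    def test_symbiosis_shift_on_logit_scale(self):
        S = np.array([[1.0, 0.0], [1.0, 1.0]])  # non-symbiotic, symbiotic
        beta_ss = -0.523
        P = linear_predictor([0.3, beta_ss], [], S, None)
        assert logit(P[1, 0]) - logit(P[0, 0]) == pytest.approx(beta_ss, abs=1e-12)

    def test_random_effects_enter_additively(self):
        S = np.ones((2, 1))
        P = linear_predictor([0.0], [], S, None, sp=[1.0, -1.0], re=[0.5, 0.0, -0.5])
        assert P.shape == (2, 3)
        assert P[0, 0] == pytest.approx(expit(1.5))
        assert P[1, 2] == pytest.approx(expit(-1.5))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            linear_predictor([0.0, 1.0], [], np.ones((3, 1)), None)


def _logistic_world(seed=31, n_species=80, n_regions=8):
    """A small world generated without random effects."""
    cfg = moderate_config(
        n_species=n_species, n_regions=n_regions, n_genera=16,
        v_species=0.0, v_region=0.0, seed=seed,
    )
    return generate_world(cfg)


class TestZeroVarianceOracle:
    def test_matches_irls_logistic_regression(self):
        import statsmodels.api as sm

        w = _logistic_world()
        model = OccupancyGLMM.from_world(w)
        res = model.fit(fix_variances={"species": 0.0, "region": 0.0})
        # independent IRLS oracle on the flattened data
        n_r = w.Y.shape[1]
        X = np.repeat(model.species_design.to_numpy(float), n_r, axis=0)
        Xr = np.tile(model.region_design.to_numpy(float), (w.Y.shape[0], 1))
        X = np.hstack([X, Xr])
        y = w.Y.to_numpy().ravel()
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-12)
        np.testing.assert_allclose(res.params.to_numpy(), glm.params, atol=1e-6)
        assert res.llf == pytest.approx(glm.llf, abs=1e-6)

    def test_toy_loglik_equals_bernoulli_loglik(self):
        # 4 species x 3 regions, variances pinned to zero
        Y = pd.DataFrame(
            [[1, 0, 0], [0, 1, 1], [0, 0, 0], [1, 1, 0]],
            index=list("abcd"), columns=["r1", "r2", "r3"],
        )
        S = pd.DataFrame(
            {"intercept": 1.0, "x": [0.2, -0.1, 0.4, 0.0]}, index=Y.index
        )
        res = OccupancyGLMM(Y, S).fit(fix_variances={"species": 0.0, "region": 0.0})
        eta = S.to_numpy() @ res.params.to_numpy()
        ll = float(
            (Y.to_numpy() * eta[:, None]).sum()
            - np.logaddexp(0, np.broadcast_to(eta[:, None], Y.shape)).sum()
        )
        assert res.llf == pytest.approx(ll, abs=1e-6)

    def test_covariate_shift_moves_only_intercept(self):
        w = _logistic_world(seed=32)
        model = OccupancyGLMM.from_world(w)
        res1 = model.fit(fix_variances={"species": 0.0, "region": 0.0})
        shifted = model.species_design.copy()
        c = 2.5
        shifted["abs_latitude"] = shifted["abs_latitude"] + c
        res2 = OccupancyGLMM(w.Y, shifted, model.region_design).fit(
            fix_variances={"species": 0.0, "region": 0.0}
        )
        b = res1.params
        b2 = res2.params
        assert b2["intercept"] == pytest.approx(b["intercept"] - c * b["abs_latitude"], abs=1e-4)
        for name in b.index:
            if name != "intercept":
                assert b2[name] == pytest.approx(b[name], abs=1e-4)

    def test_label_flip_symmetry(self):
        w = _logistic_world(seed=33)
        model = OccupancyGLMM.from_world(w, include_interaction=False)
        res1 = model.fit(fix_variances={"species": 0.0, "region": 0.0})
        flipped = model.species_design.copy()
        flipped["symbiosis"] = 1.0 - flipped["symbiosis"]
        res2 = OccupancyGLMM(w.Y, flipped, model.region_design).fit(
            fix_variances={"species": 0.0, "region": 0.0}
        )
        assert res2.params["symbiosis"] == pytest.approx(-res1.params["symbiosis"], abs=1e-5)
        assert res2.params["intercept"] == pytest.approx(
            res1.params["intercept"] + res1.params["symbiosis"], abs=1e-5
        )


class TestLaplaceFit:
    def test_zero_variance_data_estimates_near_zero_variances(self):
        w = _logistic_world(seed=34, n_species=150, n_regions=12)
        model = OccupancyGLMM.from_world(w)
        res = model.fit()
        assert res.converged
        assert res.vc["species"] < 0.05
        assert res.vc["region"] < 0.05
        # coefficients within 3 SE of the generating values
        truth = moderate_config().coefficients
        free = OccupancyGLMM.from_world(w).fit(
            fix_variances={"species": 0.0, "region": 0.0}
        )
        for name in ("symbiosis", "annual", "n_uses"):
            assert abs(res.params[name] - truth[name]) < 3 * free.bse[name]

    def test_moderate_recovery_within_three_se(self, small_world, small_fit):
        truth = small_world.config.coefficients
        for name in ("symbiosis", "annual", "woody", "n_uses", "abs_latitude"):
            assert abs(small_fit.params[name] - truth[name]) < 3 * small_fit.bse[name]

    def test_deterministic_given_data(self, small_world):
        r1 = OccupancyGLMM.from_world(small_world).fit()
        r2 = OccupancyGLMM.from_world(small_world).fit()
        pd.testing.assert_series_equal(r1.params, r2.params)
        assert r1.vc == r2.vc

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent cross-check against the reference GLMM fitter."""
        cfg = moderate_config(n_species=150, n_regions=12, n_genera=30, seed=41)
        w = generate_world(cfg)
        model = OccupancyGLMM.from_world(w)
        res = model.fit()
        long = []
        for j, rid in enumerate(w.Y.columns):
            df = model.species_design.copy()
            df["y"] = w.Y[rid].values
            df["region_area"] = model.region_design.iloc[j, 0]
            df["sp"] = w.Y.index
            df["re"] = rid
            long.append(df)
        data_path = tmp_path / "long.csv"
        pd.concat(long).to_csv(data_path, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{data_path}")
            f <- glmer(y ~ symbiosis + abs_latitude + native_area + annual + woody +
                           n_uses + symbiosis_x_uses + region_area + (1|sp) + (1|re),
                       data = d, family = binomial,
                       control = glmerControl(optimizer = "bobyqa"))
            cat(fixef(f), sep = "\\n")
            v <- as.data.frame(VarCorr(f))
            cat(v$vcov, sep = "\\n")
            """
        )
        r_file = tmp_path / "fit.R"
        r_file.write_text(script)
        out = subprocess.run(
            ["Rscript", str(r_file)], capture_output=True, text=True, timeout=600
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        lme4_beta, lme4_vc = np.array(vals[:9]), vals[9:11]
        np.testing.assert_allclose(res.params.to_numpy(), lme4_beta, atol=0.02)
        assert res.vc["species"] == pytest.approx(lme4_vc[0], abs=0.05)
        assert res.vc["region"] == pytest.approx(lme4_vc[1], abs=0.05)

    def test_separation_flagged(self):
        # a binary covariate perfectly predicting Y: complete separation
        Y = pd.DataFrame(
            np.repeat([[0], [1]], [10, 10], axis=0) * np.ones((1, 4), dtype=int),
            index=[f"s{i}" for i in range(20)], columns=list("abcd"),
        )
        S = pd.DataFrame(
            {"intercept": 1.0, "z": np.repeat([0.0, 1.0], 10)}, index=Y.index
        )
        res = OccupancyGLMM(Y, S).fit(fix_variances={"species": 0.0, "region": 0.0})
        assert res.separation_flag


class TestVariants:
    def test_subset_keeps_all_regions(self, small_world):
        model = OccupancyGLMM.from_world(small_world)
        res_all, res_nn = fit_both_variants(model)
        n_nonnative = int((small_world.Y.sum(axis=1) >= 1).sum())
        assert res_nn.model.Y.shape == (n_nonnative, small_world.Y.shape[1])
        assert res_all.model.Y.shape == small_world.Y.shape
        # cell count arithmetic: n_total = n_species_kept * n_regions
        assert res_nn.model.Y.size == n_nonnative * small_world.Y.shape[1]

    def test_identical_when_all_species_nonnative(self):
        Y = pd.DataFrame(
            [[1, 0], [0, 1], [1, 1]], index=list("abc"), columns=["r1", "r2"]
        )
        S = pd.DataFrame({"intercept": 1.0, "x": [0.1, -0.2, 0.3]}, index=Y.index)
        model = OccupancyGLMM(Y, S)
        res_all, res_nn = fit_both_variants(
            model, fix_variances={"species": 0.0, "region": 0.0}
        )
        pd.testing.assert_series_equal(res_all.params, res_nn.params)

    def test_empty_second_variant_errors(self):
        Y = pd.DataFrame(np.zeros((3, 2), dtype=int), index=list("abc"), columns=["r1", "r2"])
        S = pd.DataFrame({"intercept": 1.0}, index=Y.index)
        with pytest.raises(ValueError, match="non-native"):
            fit_both_variants(OccupancyGLMM(Y, S))


class TestContinentCheck:
    def test_no_continent_effect_recommends_removal(self):
        cfg = moderate_config(n_species=300, n_regions=24, seed=51, v_continent=0.0)
        w = generate_world(cfg)
        check = continent_check(OccupancyGLMM.from_world(w))
        assert check.identifiable
        assert check.variance < 1e-2
        assert check.recommend_removal

    def test_strong_continent_effect_retained(self):
        cfg = moderate_config(n_species=300, n_regions=24, seed=52, v_continent=2.0)
        w = generate_world(cfg)
        check = continent_check(OccupancyGLMM.from_world(w))
        assert check.variance > 0.5
        assert not check.recommend_removal

    def test_single_continent_unidentifiable(self, small_world):
        model = OccupancyGLMM.from_world(small_world)
        model.continents = pd.Series("c0", index=model.Y.columns)
        check = continent_check(model)
        assert not check.identifiable
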