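"""Binomial (mixed) incidence models: GLM, AGHQ random-intercept logit,
drop1/AIC, separation handling, mortality rates."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from tripcheck.glm import (BinomialGLM, ModelSpec, RandomInterceptLogit,
                           detect_separation, drop1_aic, mortality_rates)
from tripcheck.simulate import simulate_logistic_groups


def table_2x2(a, b, c, d):
    """Rows: factor level x, columns: response 1/0 counts."""
    rows = ([{"g": "x0", "y": 1}] * a + [{"g": "x0", "y": 0}] * b
            + [{"g": "x1", "y": 1}] * c + [{"g": "x1", "y": 0}] * d)
    return pd.DataFrame(rows)


def test_two_level_factor_equals_log_odds_ratio():
    a, b, c, d = 30, 70, 55, 45
    fit = BinomialGLM.from_dataframe(table_2x2(a, b, c, d), "y", ["g"]).fit()
    log_or = np.log((c / d) / (a / b))
    assert fit.params["g[x1]"] == pytest.approx(log_or, abs=1e-8)
    assert fit.params["Intercept"] == pytest.approx(np.log(a / b), abs=1e-8)


def test_aic_identity():
    fit = BinomialGLM.from_dataframe(table_2x2(30, 70, 55, 45), "y", ["g"]).fit()
    assert fit.aic == pytest.approx(2 * fit.nparams - 2 * fit.loglik)


def test_row_order_invariance(rng):
    df = table_2x2(30, 70, 55, 45)
    f1 = BinomialGLM.from_dataframe(df, "y", ["g"]).fit()
    f2 = BinomialGLM.from_dataframe(
        df.sample(frac=1, random_state=3), "y", ["g"]).fit()
    assert np.allclose(f1.params.to_numpy(), f2.params.to_numpy())


def test_irls_deviance_monotone():
    df = table_2x2(30, 70, 55, 45)
    import statsmodels.api as sm
    y, X, _ = BinomialGLM.from_dataframe(df, "y", ["g"]).y, None, None
    model = BinomialGLM.from_dataframe(df, "y", ["g"])
    res = sm.GLM(model.y, model.X, family=sm.families.Binomial()).fit()
    # skip the initialisation entries; IRLS proper decreases the deviance
    dev = res.fit_history["deviance"][2:]
    assert all(d2 <= d1 + 1e-8 for d1, d2 in zip(dev, dev[1:]))


def test_all_zero_response_flags_separation():
    df = pd.DataFrame({"y": [0] * 20})
    fit = BinomialGLM(df, ModelSpec(response="y")).fit()
    assert fit.separation_flag


def test_rank_deficient_design_names_aliased_columns():
    df = table_2x2(10, 10, 10, 10)
    df["g2"] = df["g"]      # perfect alias
    with pytest.raises(ValueError, match="aliased"):
        BinomialGLM.from_dataframe(df, "y", ["g", "g2"])


class TestSeparationDetection:
    def test_all_zero_level_flagged(self):
        df = pd.DataFrame({
            "treatment": ["0"] * 30 + ["9500"] * 30,
            "y": [0] * 30 + [1] * 15 + [0] * 15,
        })
        flag, offending = detect_separation(df, "y", ["treatment"])
        assert flag
        assert ("treatment", "0", 0.0) in offending

    def test_balanced_cells_not_flagged(self):
        df = pd.DataFrame({"treatment": ["a", "a", "b", "b"],
                           "y": [0, 1, 0, 1]})
        flag, offending = detect_separation(df, "y", ["treatment"])
        assert not flag and offending == []

    def test_remedy_refit_without_level_converges(self, rng):
        df = simulate_logistic_groups(10, 80, -0.5, 1.0, 0.3, rng)
        df["treatment"] = np.where(
            df["group"].isin(["g00", "g01"]), "0", "9500")
        df.loc[df["treatment"] == "0", "y"] = 0     # quasi-complete
        model = RandomInterceptLogit.from_dataframe(
            df, "y", ["treatment", "x"], "group")
        fit = model.fit()
        assert fit.separation_flag
        remedy = model.refit_without_levels({"treatment": ["0"]}).fit()
        assert remedy.converged and not remedy.separation_flag


class TestRandomInterceptLogit:
    def test_zero_variance_matches_plain_glm(self, rng):
        """Degenerate limit: at random-intercept SD 0 the marginal
        likelihood and the fixed effects are the plain GLM's."""
        df = simulate_logistic_groups(10, 150, -0.4, 0.9, 0.0, rng)
        model = RandomInterceptLogit.from_dataframe(df, "y", ["x"], "group")
        plain = BinomialGLM.from_dataframe(df, "y", ["x"]).fit()
        at_zero = model.fit(fix_re_sd=0.0)
        assert at_zero.loglik == pytest.approx(plain.loglik, abs=1e-6)
        assert np.all(np.abs(at_zero.params.to_numpy()
                             - plain.params.to_numpy()) < 1e-3)
        # and the free fit on truly ungrouped data stays near the boundary
        mixed = model.fit()
        assert mixed.re_sd < 0.2
        assert mixed.loglik >= at_zero.loglik - 1e-6

    def test_quadrature_node_convergence(self, rng):
        df = simulate_logistic_groups(8, 120, -0.3, 0.8, 0.7, rng)
        model = RandomInterceptLogit.from_dataframe(df, "y", ["x"], "group")
        fit = model.fit(n_quad=15)
        beta = fit.params.to_numpy()
        ll7 = model.loglike(beta, fit.re_sd, n_quad=7)
        ll31 = model.loglike(beta, fit.re_sd, n_quad=31)
        assert abs(ll7 - ll31) < 1e-3

    def test_laplace_close_to_aghq(self, rng):
        df = simulate_logistic_groups(8, 120, -0.3, 0.8, 0.7, rng)
        model = RandomInterceptLogit.from_dataframe(df, "y", ["x"], "group")
        aghq = model.fit()
        laplace = model.fit(method="laplace")
        assert laplace.re_sd == pytest.approx(aghq.re_sd, abs=0.05)

    def test_needs_two_groups(self):
        df = pd.DataFrame({"y": [0, 1] * 5, "x": ["a"] * 10,
                           "group": ["g"] * 10})
        with pytest.raises(ValueError, match="groups"):
            RandomInterceptLogit.from_dataframe(df, "y", [], "group")

    def test_matches_lme4_oracle(self, tmp_path, rng):
        """Independent cross-check: the same marginal likelihood maximised
        by lme4's glmer (adaptive Gauss-Hermite, nAGQ=15)."""
        df = simulate_logistic_groups(10, 100, -0.5, 1.0, 0.8, rng)
        data_path = tmp_path / "d.csv"
        df.to_csv(data_path, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{data_path}")
m <- glmer(y ~ x + (1|group), data=d, family=binomial, nAGQ=15)
fe <- fixef(m)
cat(sprintf('{{"b0": %.6f, "b1": %.6f, "sd": %.6f, "ll": %.6f}}',
    fe[1], fe[2], sqrt(as.numeric(VarCorr(m)$group)),
    as.numeric(logLik(m))))
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        oracle = json.loads(out.stdout.strip().splitlines()[-1])
        fit = RandomInterceptLogit.from_dataframe(df, "y", ["x"], "group").fit()
        assert fit.params["Intercept"] == pytest.approx(oracle["b0"], abs=2e-3)
        assert fit.params["x[b]"] == pytest.approx(oracle["b1"], abs=2e-3)
        assert fit.re_sd == pytest.approx(oracle["sd"], abs=5e-3)
        assert fit.loglik == pytest.approx(oracle["ll"], abs=1e-3)


class TestDrop1:
    def test_counts_and_identity(self, rng):
        df = simulate_logistic_groups(6, 80, -0.3, 1.0, 0.4, rng)
        df["z"] = rng.choice(["u", "v"], size=len(df))
        df["w"] = rng.choice(["p", "q"], size=len(df))
        model = RandomInterceptLogit.from_dataframe(
            df, "y", ["x", "z", "w"], "group")
        tab = drop1_aic(model)
        assert len(tab) == 4                      # full + one per fixed effect
        assert set(tab["dropped"]) == {"<none>", "x", "z", "w"}
        ok = tab.dropna(subset=["aic"])
        assert np.allclose(ok["aic"], 2 * ok["k"] - 2 * ok["loglik"])

    def test_noise_covariate_usually_dropped(self, rng):
        wins = 0
        n_sim = 300
        for _ in range(n_sim):
            df = pd.DataFrame({
                "x": rng.choice(["a", "b"], size=300),
                "noise": rng.choice(["n0", "n1"], size=300),
            })
            eta = -0.2 + 1.0 * (df["x"] == "b")
            df["y"] = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
            tab = drop1_aic(BinomialGLM.from_dataframe(df, "y",
                                                       ["x", "noise"]))
            aic_full = tab.loc[tab["dropped"] == "<none>", "aic"].iloc[0]
            aic_drop = tab.loc[tab["dropped"] == "noise", "aic"].iloc[0]
            wins += aic_drop < aic_full
        assert wins / n_sim >= 0.80

    def test_random_intercept_never_dropped(self, rng):
        df = simulate_logistic_groups(6, 60, -0.3, 1.0, 0.4, rng)
        tab = drop1_aic(RandomInterceptLogit.from_dataframe(
            df, "y", ["x"], "group"))
        assert "group" not in set(tab["dropped"])


class TestMortality:
    def test_simple_rate(self):
        df = pd.DataFrame({"unit_id": ["u"], "interval":
                           ["fertilization_to_eyed_egg"],
                           "n_start": [1000], "n_dead": [17]})
        out = mortality_rates(df)
        assert out["mortality_rate"].iloc[0] == pytest.approx(0.017)

    def test_zero_deaths(self):
        df = pd.DataFrame({"unit_id": ["u"], "interval":
                           ["eyed_egg_to_start_feed"],
                           "n_start": [500], "n_dead": [0]})
        assert mortality_rates(df)["mortality_rate"].iloc[0] == 0.0

    def test_aggregation_is_pooled_counts_not_mean_of_rates(self):
        df = pd.DataFrame({
            "treatment": ["t1", "t1"],
            "interval": ["start_feed_to_parr"] * 2,
            "n_start": [100, 900], "n_dead": [10, 9],
        })
        out = mortality_rates(df, by=["treatment"])
        assert len(out) == 1
        assert out["mortality_rate"].iloc[0] == pytest.approx(19 / 1000)
        # oracle: recompute from raw counts
        assert out["mortality_rate"].iloc[0] != pytest.approx(
            np.mean([0.10, 0.01]))

    def test_zero_start_flagged_undefined(self):
        df = pd.DataFrame({"unit_id": ["u"], "interval":
                           ["start_feed_to_parr"],
                           "n_start": [0], "n_dead": [0]})
        out = mortality_rates(df)
        assert out["undefined_rate"].iloc[0]
        assert np.isnan(out["mortality_rate"].iloc[0])

    def test_rates_bounded(self, rng):
        n = rng.integers(1, 1000, 50)
        d = (n * rng.random(50)).astype(int)
        df = pd.DataFrame({"unit_id": [f"u{i}" for i in range(50)],
                           "interval": ["eyed_egg_to_start_feed"] * 50,
                           "n_start": n, "n_dead": d})
        out = mortality_rates(df)
        assert ((out["mortality_rate"] >= 0)
                & (out["mortality_rate"] <= 1)).all()
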