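import itertools
import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import stomacomm as sc
from stomacomm.environment import MODEL_VARS
from stomacomm.lmm import (
    _prepare_responses,
    bivariate_scan,
    fit_lmm,
    hierarchical_partition,
    r2_nakagawa,
    shapley_contributions,
    vegetation_contrast,
)


def simulate_lmm(rng, n_groups=50, per_group=6, beta=2.0, sd_group=1.0, sd_resid=1.0):
    site = np.repeat(np.arange(n_groups), per_group)
    x = rng.normal(size=n_groups * per_group)
    y = (
        1.0
        + beta * x
        + np.repeat(rng.normal(0.0, sd_group, n_groups), per_group)
        + rng.normal(0.0, sd_resid, n_groups * per_group)
    )
    return pd.DataFrame({"y": y, "x": x, "site_id": site})


class TestFitLmm:
    def test_no_group_variance_reduces_to_ols(self, rng):
        df = simulate_lmm(rng, sd_group=0.0)
        fit = fit_lmm(df, "y", ["x"])
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        assert fit.singular
        assert fit.var_group == pytest.approx(0.0, abs=1e-6)
        assert fit.params["x"] == pytest.approx(ols.params.iloc[1], abs=1e-6)
        assert fit.params["Intercept"] == pytest.approx(ols.params.iloc[0], abs=1e-6)

    def test_parameter_recovery(self, rng):
        df = simulate_lmm(rng, n_groups=50, per_group=6, beta=2.0)
        fit = fit_lmm(df, "y", ["x"])
        assert abs(fit.params["x"] - 2.0) < 3 * fit.bse["x"]
        assert fit.var_group == pytest.approx(1.0, rel=0.25)
        assert fit.var_resid == pytest.approx(1.0, rel=0.25)

    def test_row_order_irrelevant(self, rng):
        df = simulate_lmm(rng)
        a = fit_lmm(df, "y", ["x"])
        b = fit_lmm(df.sample(frac=1, random_state=3), "y", ["x"])
        assert a.params["x"] == pytest.approx(b.params["x"], rel=1e-9)
        assert a.var_group == pytest.approx(b.var_group, rel=1e-7)

    def test_agrees_with_statsmodels_mixedlm(self, rng):
        df = simulate_lmm(rng, n_groups=40, per_group=6)
        fit = fit_lmm(df, "y", ["x"])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(
                df["y"].to_numpy(),
                sm.add_constant(df["x"].to_numpy()),
                groups=df["site_id"].to_numpy(),
            ).fit(reml=True)
        vg = float(np.asarray(res.cov_re)[0, 0])
        assert fit.var_group == pytest.approx(vg, rel=1e-4)
        assert fit.var_resid == pytest.approx(float(res.scale), rel=1e-4)
        assert fit.params["x"] == pytest.approx(res.fe_params[1], rel=1e-6)

    def test_agrees_with_lme4(self, rng, tmp_path):
        """Independent solver check: R lme4 on the same data."""
        df = simulate_lmm(rng, n_groups=30, per_group=5)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
            d <- read.csv("{csv}")
            m <- lmer(y ~ x + (1 | site_id), data = d, REML = TRUE)
            vc <- as.data.frame(VarCorr(m))
            cat(toJSON(list(
              beta = unname(fixef(m)),
              var_group = vc$vcov[1],
              var_resid = sigma(m)^2
            ), digits = 12))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        fit = fit_lmm(df, "y", ["x"])
        assert fit.params["Intercept"] == pytest.approx(ref["beta"][0], rel=1e-5)
        assert fit.params["x"] == pytest.approx(ref["beta"][1], rel=1e-5)
        assert fit.var_group == pytest.approx(ref["var_group"][0], rel=5e-4)
        assert fit.var_resid == pytest.approx(ref["var_resid"][0], rel=5e-4)

    def test_single_group_rejected(self, rng):
        df = simulate_lmm(rng, n_groups=1, per_group=10)
        with pytest.raises(ValueError):
            fit_lmm(df, "y", ["x"])


class TestR2Nakagawa:
    def test_intercept_only_has_zero_marginal(self, rng):
        df = simulate_lmm(rng)
        fit = fit_lmm(df, "y", [])
        r2 = r2_nakagawa(fit)
        assert r2["marginal"] == 0.0
        assert r2["conditional"] > 0.0

    def test_no_random_effect_conditional_equals_marginal(self, rng):
        df = simulate_lmm(rng, sd_group=0.0)
        r2 = r2_nakagawa(fit_lmm(df, "y", ["x"]))
        assert r2["conditional"] == pytest.approx(r2["marginal"], abs=1e-6)

    def test_known_variance_shares(self, rng):
        # var(fixed) : var(group) : var(resid) = 2 : 1 : 1
        df = simulate_lmm(
            rng, n_groups=300, per_group=10, beta=np.sqrt(2.0), sd_group=1.0
        )
        r2 = r2_nakagawa(fit_lmm(df, "y", ["x"]))
        assert r2["marginal"] == pytest.approx(0.5, abs=0.03)
        assert r2["conditional"] == pytest.approx(0.75, abs=0.03)

    def test_conditional_never_below_marginal(self, rng):
        for seed in range(5):
            df = simulate_lmm(np.random.default_rng(seed))
            r2 = r2_nakagawa(fit_lmm(df, "y", ["x"]))
            assert 0.0 <= r2["marginal"] <= r2["conditional"] <= 1.0


def _driver_tables(rng, n_sites=40, per_site=6, driver="bio18", beta=1.0):
    """Moments + env tables where one variable alone drives CWM(SD)."""
    sites = [f"s{i}" for i in range(n_sites)]
    env = pd.DataFrame({"site_id": sites})
    for v in MODEL_VARS:
        env[v] = rng.normal(size=n_sites)
    z = env[driver].to_numpy()
    rows = []
    for i, s in enumerate(sites):
        u_site = rng.normal(0.0, 0.3)
        for p in range(per_site):
            base = beta * z[i] + u_site + rng.normal(0.0, 0.3)
            for trait in ("SD", "SL", "SPI"):
                vals = {
                    "cwm": np.exp(base) if trait == "SD" else np.exp(rng.normal()),
                    "cwv": np.exp(rng.normal()),
                    "cws": rng.normal(),
                    "cwk": 3.0 + rng.normal() ** 2,
                }
                for moment, value in vals.items():
                    rows.append(
                        {
                            "plot_id": f"{s}p{p}",
                            "site_id": s,
                            "vegetation": "forest" if i % 2 else "grassland",
                            "trait": trait,
                            "moment": moment,
                            "value": value,
                            "n_species": 8,
                        }
                    )
    return pd.DataFrame(rows), env


class TestBivariateScan:
    def test_driving_variable_ranks_first(self):
        moments, env = _driver_tables(np.random.default_rng(2), driver="bio18")
        scan = bivariate_scan(moments, env, traits=["SD"])
        top = scan[(scan.trait == "SD") & (scan.moment == "cwm") & (scan["rank"] == 1)]
        assert top["env_var"].iloc[0] == "bio18"
        assert top["marginal_r2"].iloc[0] > 0.5

    def test_full_scan_row_count(self):
        moments, env = _driver_tables(np.random.default_rng(3), n_sites=20, per_site=3)
        scan = bivariate_scan(moments, env)
        assert len(scan) == 3 * 4 * 27

    def test_flat_response_flagged_with_zero_r2(self):
        moments, env = _driver_tables(np.random.default_rng(4), n_sites=15, per_site=3)
        moments.loc[
            (moments.trait == "SL") & (moments.moment == "cws"), "value"
        ] = 1.234
        scan = bivariate_scan(moments, env, env_vars=["bio1", "bio12"], traits=["SL"])
        flat = scan[(scan.moment == "cws")]
        assert flat["flat_response"].all()
        assert (flat["marginal_r2"] == 0.0).all()


def orderings_oracle(r2_by_subset, predictors):
    """Average incremental R2 by direct enumeration of all p! orderings."""
    totals = {j: 0.0 for j in predictors}
    count = 0
    for order in itertools.permutations(predictors):
        seen = frozenset()
        for j in order:
            totals[j] += r2_by_subset[seen | {j}] - r2_by_subset[seen]
            seen = seen | {j}
        count += 1
    return {j: t / count for j, t in totals.items()}


class TestHierarchicalPartition:
    def _subset_r2(self, df, predictors):
        table = {frozenset(): 0.0}
        for r in range(1, len(predictors) + 1):
            for S in itertools.combinations(predictors, r):
                fit = fit_lmm(df, "y", list(S))
                table[frozenset(S)] = r2_nakagawa(fit)["marginal"]
        return table

    def test_shapley_equals_all_orderings_enumeration(self, rng):
        preds = [f"x{i}" for i in range(6)]
        df = pd.DataFrame({p: rng.normal(size=240) for p in preds})
        df["site_id"] = np.repeat(np.arange(40), 6)
        df["y"] = (
            df[preds] @ rng.normal(size=6)
            + np.repeat(rng.normal(0, 0.8, 40), 6)
            + rng.normal(0, 1.0, 240)
        )
        table = self._subset_r2(df, preds)
        fast = shapley_contributions(table, preds)
        slow = orderings_oracle(table, preds)
        for p in preds:
            assert fast[p] == pytest.approx(slow[p], abs=1e-9)
        assert sum(fast.values()) == pytest.approx(table[frozenset(preds)], abs=1e-9)

    def test_single_predictor_share_is_full_marginal_r2(self, rng):
        df = simulate_lmm(rng)
        res = hierarchical_partition(df, "y", {"only": ["x"]})
        assert res.predictor_contributions["share_pct"].iloc[0] == pytest.approx(
            100.0 * res.marginal_r2, abs=1e-9
        )

    def test_orthogonal_predictors_split_additively(self, rng):
        n_groups, m = 60, 6
        n = n_groups * m
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # exactly orthogonal
        df = pd.DataFrame(
            {
                "x1": x1,
                "x2": x2,
                "site_id": np.repeat(np.arange(n_groups), m),
            }
        )
        df["y"] = (
            1.0 * df.x1 + 0.7 * df.x2
            + np.repeat(rng.normal(0, 0.5, n_groups), m)
            + rng.normal(0, 1.0, n)
        )
        res = hierarchical_partition(df, "y", {"g1": ["x1"], "g2": ["x2"]})
        own = {
            p: r2_nakagawa(fit_lmm(df, "y", [p]))["marginal"]
            for p in ("x1", "x2")
        }
        shares = res.predictor_contributions.set_index("predictor")["share_pct"]
        # incremental R2 is additive for orthogonal predictors (up to the
        # subset-wise re-estimation of the variance components)
        assert shares["x1"] == pytest.approx(100.0 * own["x1"], abs=2.0)
        assert shares["x2"] == pytest.approx(100.0 * own["x2"], abs=2.0)
        assert res.shares["share_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_shares_sum_to_100(self, small_dataset):
        mt = sc.moments_table(small_dataset.species_traits, small_dataset.plots)
        from stomacomm.environment import scheme_pca_scores

        scores, _ = scheme_pca_scores(small_dataset.environment, "TPS")
        data = _prepare_responses(mt).merge(scores, on="site_id")
        groups = {
            g: [f"{g}_PC1", f"{g}_PC2"]
            for g in ("temperature", "precipitation", "soil")
        }
        res = hierarchical_partition(data, "SD_cwm", groups)
        assert res.shares["share_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (res.shares["share_pct"] >= 0).all()


class TestVegetationContrast:
    def test_known_offset_recovered(self):
        rng = np.random.default_rng(8)
        delta = 0.6
        moments, _ = _driver_tables(rng, n_sites=40, per_site=6, beta=0.0)
        cwm = (moments.trait == "SD") & (moments.moment == "cwm")
        forest = moments["vegetation"] == "forest"
        moments.loc[cwm & forest, "value"] *= np.exp(delta)
        out = vegetation_contrast(moments, traits=["SD"])
        row = out[out.moment == "cwm"].iloc[0]
        assert abs(row["contrast"] - delta) < 3 * row["se"]

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(9)
        moments, _ = _driver_tables(rng, n_sites=30, per_site=4, beta=0.0)
        a = vegetation_contrast(moments, traits=["SD"])
        swapped = moments.replace(
            {"vegetation": {"forest": "grassland", "grassland": "forest"}}
        )
        b = vegetation_contrast(swapped, traits=["SD"])
        assert np.allclose(a["contrast"], -b["contrast"], rtol=1e-6)

    def test_null_contrast_is_small(self):
        rng = np.random.default_rng(10)
        moments, _ = _driver_tables(rng, n_sites=40, per_site=6, beta=0.0)
        out = vegetation_contrast(moments, traits=["SD"])
        row = out[out.moment == "cwm"].iloc[0]
        assert abs(row["contrast"]) < 3 * row["se"]

    def test_missing_level_rejected(self):
        rng = np.random.default_rng(11)
        moments, _ = _driver_tables(rng, n_sites=10, per_site=3, beta=0.0)
        only_forest = moments.assign(vegetation="forest")
        with pytest.raises(ValueError):
            vegetation_contrast(only_forest, traits=["SD"])
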