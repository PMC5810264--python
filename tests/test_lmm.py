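"""Mixed-model stage: contrasts, backend contract, pruning, reduction,
nested follow-ups, partial effects.  lme4 (via Rscript) serves as the
independent oracle for the crossed-random-effects fit."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from trialwise import (
    ModelSpec,
    fit_model,
    likelihood_ratio_test,
    nested_followup,
    partial_effects,
    prune_singular_random_terms,
    reduce_fixed_effects,
    rescale_amplitudes,
    sliding_difference_contrasts,
)


def crossed_rt_data(seed, n_participants=16, n_trials=48, n_items=4,
                    effect=-30.0, subj_sd=50.0, slope_sd=15.0,
                    item_sd=10.0, resid_sd=90.0):
    """Single-trial RTs with crossed participant/item random effects."""
    rng = np.random.default_rng(seed)
    u_p = rng.normal(0, subj_sd, n_participants)
    u_ps = rng.normal(0, slope_sd, n_participants)
    u_i = rng.normal(0, item_sd, n_items)
    rows = []
    for p in range(n_participants):
        for rep in range(n_trials):
            c = rep % 2
            it = (rep // 2) % n_items
            code = 0.5 if c else -0.5
            y = (
                470.0 + effect * code + u_p[p] + u_ps[p] * code + u_i[it]
                + rng.normal(0, resid_sd)
            )
            rows.append(
                dict(
                    participant_id=f"P{p:02d}", item_id=f"I{it}",
                    pc=["blurred", "intact"][c], y=y,
                )
            )
    return pd.DataFrame(rows)


CROSSED_SPEC = ModelSpec(
    response="y",
    fixed=["pc"],
    random={"participant_id": ["1", "pc"], "item_id": ["1"]},
)


class TestSlidingDifferenceContrasts:
    def test_two_levels_half_codes(self):
        c = sliding_difference_contrasts(2)
        assert np.allclose(c, [[-0.5], [0.5]])

    def test_two_level_effect_is_mean_difference(self):
        # balanced toy data: OLS with the contrast recovers mu2 - mu1 and
        # the intercept recovers the grand mean
        y = np.array([1.0, 3.0, 7.0, 9.0])  # level1: 1,3; level2: 7,9
        codes = np.array([-0.5, -0.5, 0.5, 0.5])
        X = np.column_stack([np.ones(4), codes])
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.isclose(b[0], 5.0)  # grand mean
        assert np.isclose(b[1], 6.0)  # 8 - 2

    def test_three_levels_successive_differences(self):
        mu = np.array([2.0, 5.0, 11.0])
        C = sliding_difference_contrasts(3)
        X = np.column_stack([np.ones(3), C])
        b = np.linalg.solve(X.T @ X, X.T @ mu)
        assert np.isclose(b[0], mu.mean())
        assert np.allclose(b[1:], [3.0, 6.0])

    @given(st.integers(2, 8))
    def test_columns_sum_to_zero(self, k):
        assert np.allclose(sliding_difference_contrasts(k).sum(axis=0), 0.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            sliding_difference_contrasts(1)


class TestFitModel:
    def test_recovers_reference_magnitude_effect_across_seeds(self):
        # fixed RT effect -30 ms, random SDs 50/15, residual 90 ms
        hits = 0
        for seed in range(20):
            df = crossed_rt_data(seed)
            fit = fit_model(CROSSED_SPEC, df)
            b = fit.fixed_effects.loc["pc[intact-blurred]"]
            if abs(b["b"] - (-30.0)) <= 3 * b["se"]:
                hits += 1
        assert hits >= 18  # >= 90% of 20 seeded runs

    def test_interval_coverage_near_nominal(self):
        # 95% Wald intervals for the fixed effect should cover the truth in
        # [90%, 99%] of 200 simulated fits
        cover = 0
        for seed in range(200):
            rng = np.random.default_rng(40000 + seed)
            u = rng.normal(0, 50, 10)
            rows = []
            for p in range(10):
                for rep in range(32):
                    c = rep % 2
                    code = 0.5 if c else -0.5
                    rows.append(
                        dict(
                            participant_id=p, pc=["blurred", "intact"][c],
                            y=470 - 30 * code + u[p] + rng.normal(0, 90),
                        )
                    )
            fit = fit_model(
                ModelSpec(
                    response="y", fixed=["pc"],
                    random={"participant_id": ["1"]},
                ),
                pd.DataFrame(rows),
            )
            row = fit.fixed_effects.loc["pc[intact-blurred]"]
            if abs(row["b"] + 30.0) <= 1.96 * row["se"]:
                cover += 1
        assert 0.90 * 200 <= cover <= 0.99 * 200

    def test_zero_random_variance_equals_ols(self):
        rng = np.random.default_rng(0)
        df = crossed_rt_data(1, subj_sd=0.0, slope_sd=0.0, item_sd=0.0)
        fit = fit_model(CROSSED_SPEC, df)
        import statsmodels.api as sm

        codes = np.where(df["pc"] == "intact", 0.5, -0.5)
        X = np.column_stack([np.ones(len(df)), codes])
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        assert np.allclose(
            fit.fixed_effects["b"].to_numpy(), ols.params, atol=1e-4
        )

    def test_constant_response_degenerate(self):
        df = crossed_rt_data(2)
        df["y"] = 5.0
        fit = fit_model(CROSSED_SPEC, df)
        assert fit.fixed_effects.loc["Intercept", "b"] == 5.0
        assert fit.fixed_effects["b"].drop("Intercept").abs().max() == 0.0
        assert fit.resid_sd == 0.0

    def test_binomial_recovers_logit_effect(self):
        rng = np.random.default_rng(5)
        n_p = 24
        u = rng.normal(0, 0.9, n_p)
        rows = []
        for p in range(n_p):
            for rep in range(100):
                c = rep % 2
                code = 0.5 if c else -0.5
                eta = 1.2 + 1.0 * code + u[p]
                rows.append(
                    dict(
                        participant_id=p,
                        pc=["blurred", "intact"][c],
                        acc=int(rng.random() < 1 / (1 + np.exp(-eta))),
                    )
                )
        df = pd.DataFrame(rows)
        fit = fit_model(
            ModelSpec(
                response="acc", fixed=["pc"],
                random={"participant_id": ["1"]}, family="binomial",
            ),
            df,
        )
        row = fit.fixed_effects.loc["pc[intact-blurred]"]
        assert abs(row["b"] - 1.0) <= 3 * row["se"]
        assert np.isnan(fit.aic)  # no marginal likelihood for binomial VB

    def test_binomial_requires_binary_response(self):
        df = crossed_rt_data(3)
        with pytest.raises(ValueError, match="0/1"):
            fit_model(
                ModelSpec(
                    response="y", fixed=["pc"], random={}, family="binomial"
                ),
                df,
            )

    def test_missing_column_reported(self):
        df = crossed_rt_data(3)
        with pytest.raises(KeyError, match="nope"):
            fit_model(ModelSpec(response="nope", fixed=["pc"]), df)


@pytest.mark.skipif(
    shutil.which("Rscript") is None, reason="Rscript not available"
)
class TestLme4Oracle:
    def test_crossed_fit_matches_lme4(self, tmp_path):
        df = crossed_rt_data(7)
        fit = fit_model(CROSSED_SPEC, df, reml=True)
        csv = tmp_path / "d.csv"
        out = tmp_path / "lme4.csv"
        d2 = df.copy()
        d2["code"] = np.where(d2["pc"] == "intact", 0.5, -0.5)
        d2.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(y ~ code + (1|participant_id) + (0+code|participant_id)
                  + (1|item_id), data=d, REML=TRUE)
        co <- summary(m)$coefficients
        sds <- as.data.frame(VarCorr(m))
        write.csv(data.frame(
            b0=co[1,1], b1=co[1,2], c0=co[2,1], c1=co[2,2],
            llf=as.numeric(logLik(m)),
            sd_int=sds$sdcor[sds$grp=="participant_id"][1]
        ), "{out}", row.names=FALSE)
        """
        subprocess.run(
            ["Rscript", "-e", script], check=True, capture_output=True
        )
        ref = pd.read_csv(out).iloc[0]
        fe = fit.fixed_effects
        assert np.isclose(fe.loc["Intercept", "b"], ref["b0"], atol=1e-2)
        assert np.isclose(fe.loc["Intercept", "se"], ref["b1"], rtol=1e-2)
        assert np.isclose(
            fe.loc["pc[intact-blurred]", "b"], ref["c0"], atol=1e-2
        )
        assert np.isclose(
            fe.loc["pc[intact-blurred]", "se"], ref["c1"], rtol=1e-2
        )
        assert np.isclose(fit.llf, ref["llf"], atol=1e-2)
        sd_int = fit.random_sd.query(
            "grouping == 'participant_id' and term == '1'"
        )["sd"].iloc[0]
        assert np.isclose(sd_int, ref["sd_int"], rtol=0.02)


class TestPruning:
    def test_null_item_slope_pruned_more_than_real_terms(self):
        spec = ModelSpec(
            response="y", fixed=["pc"],
            random={"participant_id": ["1", "pc"], "item_id": ["1", "pc"]},
        )
        item_slope_removed = participant_removed = 0
        for seed in range(20):
            df = crossed_rt_data(
                seed + 300, n_participants=12, n_trials=256, n_items=8
            )
            _, removed, _ = prune_singular_random_terms(spec, df)
            if "item_id:pc" in removed:
                item_slope_removed += 1
            if any(r.startswith("participant_id") for r in removed):
                participant_removed += 1
        # a truly-zero variance hits the REML boundary in roughly half of
        # datasets; real components should essentially never be pruned
        assert item_slope_removed >= 6
        assert participant_removed <= 2

    def test_substantial_variances_leave_spec_unchanged(self):
        df = crossed_rt_data(9, subj_sd=80.0, slope_sd=40.0, item_sd=30.0)
        spec2, removed, fit = prune_singular_random_terms(CROSSED_SPEC, df)
        assert removed == []
        assert spec2.random == CROSSED_SPEC.random

    def test_deterministic(self):
        df = crossed_rt_data(10, item_sd=0.0)
        spec = ModelSpec(
            response="y", fixed=["pc"],
            random={"participant_id": ["1", "pc"], "item_id": ["1"]},
        )
        r1 = prune_singular_random_terms(spec, df)[1]
        r2 = prune_singular_random_terms(spec, df)[1]
        assert r1 == r2

    def test_intercept_removed_only_after_slopes(self):
        df = crossed_rt_data(11, item_sd=0.0)
        spec = ModelSpec(
            response="y", fixed=["pc"],
            random={"participant_id": ["1", "pc"], "item_id": ["1", "pc"]},
        )
        _, removed, _ = prune_singular_random_terms(spec, df)
        if "item_id:1" in removed:
            assert removed.index("item_id:pc") < removed.index("item_id:1")


def three_way_data(seed, b_ab=40.0, b_ac=40.0, n_participants=12, n_trials=96):
    """Null 3-way interaction; strong 2-way interactions and main effects."""
    rng = np.random.default_rng(seed)
    u_p = rng.normal(0, 50, n_participants)
    rows = []
    for p in range(n_participants):
        for rep in range(n_trials):
            a, b, c = rep % 2, (rep // 2) % 2, (rep // 4) % 2
            ca, cb, cc = a - 0.5, b - 0.5, c - 0.5
            y = (
                470 - 30 * ca - 15 * cb + b_ab * ca * cb + b_ac * ca * cc
                + u_p[p] + rng.normal(0, 90)
            )
            rows.append(
                dict(
                    participant_id=p, A=f"a{a}", B=f"b{b}", C=f"c{c}", y=y
                )
            )
    return pd.DataFrame(rows)


class TestReduction:
    def test_null_three_way_removed_real_two_ways_kept(self):
        spec = ModelSpec(
            response="y", fixed=["A*B*C"], random={"participant_id": ["1"]}
        )
        removed_3way = kept_2ways = 0
        for seed in range(50):
            fit, trail = reduce_fixed_effects(spec, three_way_data(seed))
            removed = {c.removed_term for c in trail if c.preferred == "small"}
            if "A:B:C" in removed:
                removed_3way += 1
            if "A:B" in fit.column_terms and "A:C" in fit.column_terms:
                kept_2ways += 1
        assert removed_3way >= 40  # >= 80% of 50 runs
        assert kept_2ways >= 40

    def test_strongly_supported_terms_not_removed(self):
        df = three_way_data(0, b_ab=80.0, b_ac=80.0)
        # make even C's main effect strong through the retained interactions
        spec = ModelSpec(
            response="y", fixed=["A", "B", "A:B"],
            random={"participant_id": ["1"]},
        )
        fit, trail = reduce_fixed_effects(spec, df)
        assert "A:B" in fit.column_terms
        assert all(c.preferred != "small" or c.removed_term is None
                   for c in trail if c.removed_term == "A:B")

    def test_lrt_statistic_identity(self):
        df = crossed_rt_data(13)
        big = fit_model(
            ModelSpec(response="y", fixed=["pc"],
                      random={"participant_id": ["1"]}),
            df, reml=False,
        )
        small = fit_model(
            ModelSpec(response="y", fixed=[],
                      random={"participant_id": ["1"]}),
            df, reml=False,
        )
        cmp_ = likelihood_ratio_test(big, small)
        assert np.isclose(
            cmp_.delta_chi2, 2 * (big.llf - small.llf), atol=1e-8
        )
        assert cmp_.df == 1


class TestNestedFollowup:
    def _data(self, seed, eff_l1=2.0, eff_l2=0.0):
        rng = np.random.default_rng(seed)
        u_p = rng.normal(0, 1.0, 20)
        rows = []
        for p in range(20):
            for rep in range(80):
                inner = rep % 2
                outer = (rep // 2) % 2
                ci = inner - 0.5
                eff = eff_l1 if outer == 0 else eff_l2
                y = ci * eff + u_p[p] + rng.normal(0, 2.0)
                rows.append(
                    dict(
                        participant_id=p, inner=f"i{inner}",
                        outer=f"o{outer}", y=y,
                    )
                )
        return pd.DataFrame(rows)

    SPEC = ModelSpec(
        response="y", fixed=["inner*outer"],
        random={"participant_id": ["1"]},
    )

    def test_recovers_per_level_effects(self):
        nf = nested_followup(self.SPEC, self._data(1), "inner", "outer")
        b1 = nf.loc[nf["outer_level"] == "o0"].iloc[0]
        b2 = nf.loc[nf["outer_level"] == "o1"].iloc[0]
        assert abs(b1["b"] - 2.0) <= 3 * b1["se"]
        assert abs(b2["b"] - 0.0) <= 3 * b2["se"]

    def test_symmetric_effects_agree(self):
        nf = nested_followup(
            self.SPEC, self._data(2, eff_l1=1.5, eff_l2=1.5),
            "inner", "outer",
        )
        b = nf["b"].to_numpy()
        se = nf["se"].to_numpy()
        assert abs(b[0] - b[1]) <= 3 * np.hypot(se[0], se[1])

    def test_mean_of_nested_equals_main_effect_on_balanced_data(self):
        df = self._data(3, eff_l1=2.0, eff_l2=1.0)
        nf = nested_followup(self.SPEC, df, "inner", "outer")
        full = fit_model(self.SPEC, df)
        main = full.fixed_effects.loc["inner[i1-i0]", "b"]
        assert np.isclose(nf["b"].mean(), main, atol=1e-2)

    def test_empty_level_is_error(self):
        df = self._data(4)
        df = df[df["outer"] != "o1"]
        spec = ModelSpec(
            response="y", fixed=["inner*outer"],
            random={"participant_id": ["1"]},
            factors={"outer": ["o0", "o1"], "inner": ["i0", "i1"]},
        )
        with pytest.raises(ValueError, match="o1"):
            nested_followup(spec, df, "inner", "outer")


class TestPartialEffects:
    def test_keep_everything_is_identity(self):
        df = crossed_rt_data(20)
        fit = fit_model(CROSSED_SPEC, df)
        assert np.allclose(partial_effects(fit), fit._y)

    def test_remove_everything_gives_residuals(self):
        df = crossed_rt_data(21)
        fit = fit_model(CROSSED_SPEC, df)
        resid = partial_effects(fit, keep_fixed=[], remove_random=True)
        fitted = (
            fit._X.to_numpy() @ fit.fixed_effects["b"].to_numpy()
            + fit._random_contrib
        )
        assert np.allclose(resid, fit._y - fitted)

    def test_partialing_out_nuisance_recovers_covariate_slope(self):
        rng = np.random.default_rng(22)
        n = 1500
        x = rng.normal(size=n)
        nuisance = rng.choice([-0.5, 0.5], size=n)
        y = 2.0 * x + 30.0 * nuisance + rng.normal(0, 3.0, n)
        df = pd.DataFrame(
            {
                "y": y, "x": x,
                "nz": np.where(nuisance > 0, "hi", "lo"),
                "participant_id": np.repeat(np.arange(10), n // 10),
            }
        )
        fit = fit_model(
            ModelSpec(
                response="y", fixed=["x", "nz"],
                random={"participant_id": ["1"]},
            ),
            df,
        )
        adj = partial_effects(fit, keep_fixed=["Intercept", "x"])
        slope = np.polyfit(x, adj, 1)[0]
        se = 3.0 / (np.std(x) * np.sqrt(n))
        assert abs(slope - 2.0) <= 3 * se

    def test_unknown_term_rejected(self):
        fit = fit_model(CROSSED_SPEC, crossed_rt_data(23))
        with pytest.raises(KeyError):
            partial_effects(fit, keep_fixed=["nope"])


class TestRescale:
    def test_divides_by_factor(self):
        df = pd.DataFrame({"amp": [15.0, -5.0]})
        out = rescale_amplitudes(df, "amp")
        assert out["amp"].tolist() == [1.5, -0.5]

    def test_factor_one_is_identity(self):
        df = pd.DataFrame({"amp": [1.0, 2.0]})
        assert rescale_amplitudes(df, "amp", 1.0)["amp"].tolist() == [1.0, 2.0]

    def test_slope_scales_inversely_in_ols_limit(self):
        rng = np.random.default_rng(30)
        n = 400
        amp = rng.normal(0, 10, n)
        y = 3.0 * amp + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "amp": amp})
        raw = fit_model(ModelSpec(response="y", fixed=["amp"]), df)
        scaled = fit_model(
            ModelSpec(response="y", fixed=["amp"]),
            rescale_amplitudes(df, "amp", 10.0),
        )
        assert np.isclose(
            scaled.fixed_effects.loc["amp", "b"],
            10 * raw.fixed_effects.loc["amp", "b"],
            rtol=1e-6,
        )
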