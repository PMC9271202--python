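"""Scaling, mixed-model fitting and single-step max-t inference."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lulcrisk import (
    build_contrast_set,
    center_scale,
    classify_significance,
    fit_lmm,
    run_effects,
    single_step_contrasts,
)
from lulcrisk.effects import ContrastSet, QMCSettings

from conftest import ECO_CLASSES, balanced_sites, synthetic_lmm_fit


class TestCenterScale:
    def test_simple_column(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        scaled = center_scale(df, ["x"])
        assert np.allclose(scaled.data["x"], [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        df = pd.DataFrame({"x": x})
        scaled = center_scale(df, ["x"])
        assert np.allclose(scaled.data["x"], x, atol=1e-10)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.gamma(2, 3, size=40)})
        scaled = center_scale(df, ["x"])
        back = scaled.unscale("x", scaled.data["x"])
        assert np.allclose(back, df["x"], atol=1e-10)

    def test_scaled_invariants(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.uniform(0, 100, 80), "y": rng.normal(5, 2, 80)})
        df.loc[3:7, "y"] = np.nan
        scaled = center_scale(df, ["x", "y"])
        for v in ("x", "y"):
            col = scaled.data[v].dropna()
            assert abs(col.mean()) < 1e-10
            assert abs(col.std(ddof=1) - 1) < 1e-10

    def test_zero_sd_column_named_in_error(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            center_scale(df, ["flat"])


class TestFitLMM:
    def test_matches_ols_class_differences_under_zero_variance(self):
        # no covariates, balanced classes, per-site catchments and zero
        # shared variance: GLS reduces to OLS on class means
        shift = {"UF": 0.0, "LF": -0.3, "LBF": -0.6, "SFy": -1.0,
                 "SFo": -0.2, "PA": -2.0, "MA": -2.5}
        df = balanced_sites(n_per_class=10, class_shift=shift, seed=7)
        fit = fit_lmm(df, "y", covariates=())
        means = df.groupby("lulc")["y"].mean()
        for c in ECO_CLASSES[1:]:
            est = fit.beta[f"C(lulc, Treatment('UF'))[T.{c}]"]
            assert est == pytest.approx(means[c] - means["UF"], abs=1e-6)

    def test_invariant_to_balanced_replication(self):
        df = balanced_sites(n_per_class=8, seed=3)
        doubled = pd.concat([df, df.assign(site_id=df.site_id + "_dup")], ignore_index=True)
        f1 = fit_lmm(df, "y", covariates=())
        f2 = fit_lmm(doubled, "y", covariates=())
        assert np.allclose(f1.beta, f2.beta, atol=1e-5)

    def test_missing_class_listed_in_error(self):
        df = balanced_sites(n_per_class=4, seed=1)
        df = df[df.lulc != "MA"]
        with pytest.raises(ValueError, match="MA"):
            fit_lmm(df, "y", covariates=(), require_classes=ECO_CLASSES)

    def test_fewer_than_two_classes_rejected(self):
        df = balanced_sites(n_per_class=4, seed=1)
        df = df[df.lulc == "UF"]
        with pytest.raises(ValueError, match="2 classes"):
            fit_lmm(df, "y", covariates=())

    def test_variance_components_recovered_roughly(self):
        df = balanced_sites(
            n_per_class=40, var_catchment=1.0, sd_resid=1.0,
            per_site_catchments=False, seed=11,
        )
        fit = fit_lmm(df, "y", covariates=(), random=("catchment",))
        assert 0.3 < fit.vcomp["catchment"] < 3.0
        assert 0.7 < fit.vcomp["residual"] < 1.4

    def test_standardization_equivalence(self):
        shift = {c: -0.4 * i for i, c in enumerate(ECO_CLASSES)}
        df = balanced_sites(n_per_class=12, class_shift=shift,
                            var_catchment=0.3, per_site_catchments=False, seed=5)
        raw = fit_lmm(df, "y", covariates=(), random=("catchment",))
        scaled = center_scale(df, ["y"])
        std = fit_lmm(scaled.data, "y", covariates=(), random=("catchment",))
        sd = scaled.sds["y"]
        for c in ECO_CLASSES[1:]:
            name = f"C(lulc, Treatment('UF'))[T.{c}]"
            assert std.beta[name] == pytest.approx(raw.beta[name] / sd, abs=1e-6)


class TestSingleStep:
    def test_single_contrast_equals_unadjusted_normal_p(self):
        fit = synthetic_lmm_fit(beta_values=[0.0, 0.5, -0.2, 0.1, 0.3, -1.0, -1.5])
        cset = build_contrast_set([("UF", "PA")], bidirectional=())
        res = single_step_contrasts(fit, cset)
        z = res["z"].iloc[0]
        assert res["p_adjusted"].iloc[0] == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-6)
        assert res.attrs["q_crit"] == pytest.approx(stats.norm.ppf(0.975), abs=1e-12)

    def test_independent_contrasts_match_sidak(self):
        # identity fixed-effect covariance and contrasts on disjoint
        # coefficients give a diagonal correlation matrix
        fit = synthetic_lmm_fit(beta_values=[0.0, 1.2, 0.0, -0.4, 1.5, 0.0, 2.2])
        cset = build_contrast_set(
            [("UF", "LF"), ("SFy", "SFo"), ("PA", "MA")], bidirectional=()
        )
        res = single_step_contrasts(fit, cset)
        k = 3
        for _, row in res.iterrows():
            sidak = 1 - (1 - row["p_unadjusted"]) ** k
            assert row["p_adjusted"] == pytest.approx(sidak, abs=1e-3)

    def test_perfectly_correlated_contrasts_equal_unadjusted(self):
        fit = synthetic_lmm_fit(beta_values=[0.0, 0.8, 0, 0, 0, 0, 0])
        matrix = pd.DataFrame(
            [
                {"UF": -1.0, "LF": 1.0, "LBF": 0, "SFy": 0, "SFo": 0, "PA": 0, "MA": 0},
                {"UF": 1.0, "LF": -1.0, "LBF": 0, "SFy": 0, "SFo": 0, "PA": 0, "MA": 0},
            ],
            index=["UF->LF", "LF->UF"],
        )
        res = single_step_contrasts(fit, ContrastSet(matrix))
        for _, row in res.iterrows():
            assert row["p_adjusted"] == pytest.approx(row["p_unadjusted"], abs=2e-3)

    def test_adding_contrasts_never_decreases_adjusted_p(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(7, 7))
        cov = A @ A.T + 7 * np.eye(7)
        fit = synthetic_lmm_fit(cov=cov, beta_values=rng.normal(size=7))
        small = build_contrast_set([("UF", "PA"), ("UF", "MA")], bidirectional=())
        large = build_contrast_set(
            [("UF", "PA"), ("UF", "MA"), ("LF", "PA"), ("SFy", "SFo"), ("PA", "MA")],
            bidirectional=(),
        )
        r_small = single_step_contrasts(fit, small).set_index("transition")
        r_large = single_step_contrasts(fit, large).set_index("transition")
        for t in r_small.index:
            assert r_large.loc[t, "p_adjusted"] >= r_small.loc[t, "p_adjusted"] - 2e-3

    def test_bounds_and_simultaneous_ci(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(7, 7))
        fit = synthetic_lmm_fit(cov=A @ A.T + 7 * np.eye(7),
                                beta_values=rng.normal(size=7))
        res = single_step_contrasts(fit, build_contrast_set())
        k = len(res)
        assert (res["p_adjusted"] >= res["p_unadjusted"] - 1e-12).all()
        assert (res["p_adjusted"] <= np.minimum(1.0, k * res["p_unadjusted"]) + 1e-12).all()
        assert ((res["ci_lower"] <= res["estimate"]) & (res["estimate"] <= res["ci_upper"])).all()
        assert res.attrs["q_crit"] >= stats.norm.ppf(0.975)  # wider than unadjusted

    def test_contrast_rows_must_sum_to_zero(self):
        bad = pd.DataFrame([{c: 1.0 for c in ECO_CLASSES}], index=["bad"])
        with pytest.raises(ValueError, match="sum to 0"):
            ContrastSet(bad)

    def test_contrast_on_absent_class_rejected(self):
        df = balanced_sites(n_per_class=5, seed=2)
        df = df[df.lulc != "SFo"]
        fit = fit_lmm(df, "y", covariates=())
        with pytest.raises(ValueError, match="SFo"):
            single_step_contrasts(fit, build_contrast_set())

    def test_direction_classification(self):
        res = pd.DataFrame(
            {"estimate": [0.8, -0.8, 0.8], "p_adjusted": [0.001, 0.001, 0.20]}
        )
        assert list(classify_significance(res, 0.05)) == ["increase", "decrease", "none"]


class TestRunEffects:
    def test_tidy_output_and_single_region_fallback(self, eco_sites):
        effects, meta = run_effects(
            eco_sites,
            ["richness_birds", "richness_orchid_bees"],
            qmc_settings=QMCSettings(n=2**11, reps=4, tol=5e-3),
        )
        assert len(effects) == 30  # 15 contrasts x 2 variables
        assert meta["richness_birds"]["random"] == ("catchment", "region")
        assert meta["richness_orchid_bees"]["random"] == ("catchment",)
        assert set(effects["direction"]) <= {"increase", "decrease", "none"}

    def test_known_large_effects_detected_with_correct_sign(self, eco_sites):
        effects, _ = run_effects(
            eco_sites, ["carbon_aboveground"],
            qmc_settings=QMCSettings(n=2**11, reps=4, tol=5e-3),
        )
        e = effects.set_index("transition")
        # deforestation of undisturbed forest wipes out above-ground carbon
        assert e.loc["UF->PA", "direction"] == "decrease"
        assert e.loc["UF->MA", "direction"] == "decrease"
        # secondary-forest ageing accumulates carbon
        assert e.loc["SFy->SFo", "direction"] == "increase"


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstR:
    def test_lmer_and_multcomp_agreement(self, tmp_path):
        """Cross-check the mixed-model fit against lme4 and the max-t
        machinery against multcomp on the same inputs."""
        rng = np.random.default_rng(11)
        rows = []
        for ci, c in enumerate(ECO_CLASSES):
            for j in range(12):
                rows.append(
                    dict(
                        site_id=f"s{ci}_{j}", catchment=f"c{rng.integers(0, 12)}",
                        region="PGM", lulc=c,
                        clay=rng.uniform(), elevation=rng.uniform(), slope=rng.uniform(),
                        y=rng.normal(loc=-0.5 * ci / 6),
                    )
                )
        df = pd.DataFrame(rows)
        df.to_csv(tmp_path / "data.csv", index=False)
        fit = fit_lmm(df, "y", random=("catchment",))
        cset = build_contrast_set()
        res = single_step_contrasts(fit, cset)

        fit.beta.to_csv(tmp_path / "beta.csv")
        fit.cov_beta.to_csv(tmp_path / "vcov.csv")
        C = np.stack(
            [
                sum((w * fit.class_vector(cl).to_numpy() for cl, w in row.items() if w != 0),
                    start=np.zeros(len(fit.beta)))
                for _, row in cset.matrix.iterrows()
            ]
        )
        pd.DataFrame(C, index=cset.labels, columns=fit.beta.index).to_csv(tmp_path / "K.csv")

        script = textwrap.dedent("""
            suppressMessages({library(lme4); library(multcomp)})
            df <- read.csv("data.csv")
            df$lulc <- relevel(factor(df$lulc), ref="UF")
            m <- lmer(y ~ lulc + clay + elevation + slope + (1|catchment),
                      data=df, REML=TRUE)
            vc <- as.data.frame(VarCorr(m))
            fe <- data.frame(name=names(fixef(m)), value=as.numeric(fixef(m)))
            write.csv(fe, "r_fixef.csv", row.names=FALSE)
            write.csv(data.frame(grp=vc$grp, vcov=vc$vcov), "r_vc.csv", row.names=FALSE)
            beta_df <- read.csv("beta.csv", row.names=1)
            beta <- beta_df[,1]; names(beta) <- rownames(beta_df)
            V <- as.matrix(read.csv("vcov.csv", row.names=1))
            colnames(V) <- rownames(V); V <- (V + t(V)) / 2
            K <- as.matrix(read.csv("K.csv", row.names=1))
            colnames(K) <- rownames(V)
            set.seed(1)
            g <- glht(parm(beta, V), linfct=K)
            s <- summary(g, test=adjusted("single-step"))
            ci <- confint(g)
            out <- data.frame(transition=rownames(K),
                              estimate=s$test$coefficients,
                              p_adj=s$test$pvalues,
                              lo=ci$confint[,"lwr"], hi=ci$confint[,"upr"])
            write.csv(out, "r_glht.csv", row.names=FALSE)
        """)
        (tmp_path / "xcheck.R").write_text(script)
        subprocess.run(
            ["Rscript", "xcheck.R"], cwd=tmp_path, check=True,
            capture_output=True, text=True,
        )

        r_fixef = pd.read_csv(tmp_path / "r_fixef.csv")
        r_pa = r_fixef.set_index("name")["value"]["lulcPA"]
        assert fit.beta["C(lulc, Treatment('UF'))[T.PA]"] == pytest.approx(r_pa, abs=1e-4)
        r_vc = pd.read_csv(tmp_path / "r_vc.csv").set_index("grp")["vcov"]
        assert fit.vcomp["residual"] == pytest.approx(r_vc["Residual"], rel=1e-3)

        r_glht = pd.read_csv(tmp_path / "r_glht.csv")
        merged = res.merge(r_glht, on="transition")
        assert np.allclose(merged["estimate_x"], merged["estimate_y"], atol=1e-6)
        # both sides carry their own Monte-Carlo integration error
        assert (merged["p_adjusted"] - merged["p_adj"]).abs().max() < 5e-3
        assert (merged["ci_lower"] - merged["lo"]).abs().max() < 2e-2
        assert (merged["ci_upper"] - merged["hi"]).abs().max() < 2e-2
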