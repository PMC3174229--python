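import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathrise.range_models import (
    LrTestResult,
    ModelSpec,
    boundary_lr_test,
    build_model_frame,
    diagnostics,
    fit_mixed,
    select_fixed_structure,
    select_random_structure,
    seminatural_contrasts,
)


def oneway_frame(seed, n_groups=40, per_group=8, group_sd=0.6, resid_sd=1.0,
                 slope=0.0, mean=1.5):
    """Balanced one-way random-intercept data on the model-frame schema."""
    r = np.random.default_rng(seed)
    n = n_groups * per_group
    g = np.repeat(np.arange(n_groups), per_group)
    geff = r.normal(0, group_sd, n_groups)
    srt = np.sqrt(r.uniform(5, 120, n))
    y = mean + slope * srt + geff[g] + r.normal(0, resid_sd, n)
    df = pd.DataFrame(
        {
            "log_habitats_seminatural": y,
            "sqrt_rt": srt,
            "genus": [f"g{i:03d}" for i in g],
            "contaminant_vs_rest": r.integers(0, 2, n),
        }
    )
    df["family"] = pd.Series(g // 2).map(lambda f: f"f{f:02d}")
    df["order"] = pd.Series(g // 4).map(lambda o: f"o{o:02d}")
    return df


class TestFitMixed:
    def test_balanced_anova_closed_form(self):
        """REML group variance on a balanced one-way design equals the
        method-of-moments estimator (MSB - MSW) / n_per_group."""
        df = oneway_frame(0, n_groups=30, per_group=6, slope=0.0)
        df = df.drop(columns=["sqrt_rt"])
        fit = fit_mixed(df, ModelSpec(fixed=[], random="genus_only"))
        y = df["log_habitats_seminatural"].to_numpy().reshape(30, 6)
        msb = 6 * y.mean(axis=1).var(ddof=1)
        msw = y.var(axis=1, ddof=1).mean()
        assert fit.variance_components["genus"] == pytest.approx(
            (msb - msw) / 6, abs=1e-6
        )
        assert fit.variance_components["residual"] == pytest.approx(msw, abs=1e-3)

    def test_fast_path_matches_statsmodels(self):
        df = oneway_frame(1)
        for est in ("REML", "ML"):
            spec = ModelSpec(fixed=["sqrt_rt"], random="genus_only", estimation=est)
            fast = fit_mixed(df, spec)
            ref = fit_mixed(df, spec, engine="statsmodels")
            assert fast.loglik == pytest.approx(ref.loglik, abs=1e-5)
            assert fast.variance_components["genus"] == pytest.approx(
                ref.variance_components["genus"], abs=1e-4
            )
            assert np.allclose(
                fast.fixed_estimates["coef"], ref.fixed_estimates["coef"], atol=1e-5
            )

    def test_zero_group_variance_at_boundary(self):
        df = oneway_frame(2, group_sd=0.0)
        fit = fit_mixed(df, ModelSpec(fixed=["sqrt_rt"], random="genus_only"))
        assert fit.variance_components["genus"] == pytest.approx(0.0, abs=0.02)

    def test_reml_ml_fixed_effects_agree_on_balanced_design(self):
        df = oneway_frame(3)
        reml = fit_mixed(df, ModelSpec(fixed=[], random="genus_only", estimation="REML"))
        ml = fit_mixed(df, ModelSpec(fixed=[], random="genus_only", estimation="ML"))
        assert np.allclose(
            reml.fixed_estimates["coef"], ml.fixed_estimates["coef"], atol=1e-6
        )

    def test_aic_identity(self):
        df = oneway_frame(4)
        fit = fit_mixed(df, ModelSpec(fixed=["sqrt_rt"], random="genus_only"))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params, abs=1e-9)

    def test_non_nested_taxonomy_rejected(self):
        df = oneway_frame(5)
        df.loc[0, "family"] = "elsewhere"
        with pytest.raises(ValueError, match="nested"):
            fit_mixed(df, ModelSpec(fixed=[], random="genus_only"))


class TestBoundaryLr:
    def test_corrected_p_is_half_nominal(self):
        t = boundary_lr_test(-100.0, -98.0)
        assert t.statistic == pytest.approx(4.0)
        assert t.p_value == pytest.approx(0.5 * stats.chi2.sf(4.0, 1), abs=1e-12)
        assert t.boundary_corrected

    def test_adding_component_never_decreases_reml_loglik(self):
        df = oneway_frame(6)
        f0 = fit_mixed(df, ModelSpec(fixed=["sqrt_rt"], random="none"))
        f1 = fit_mixed(df, ModelSpec(fixed=["sqrt_rt"], random="order"))
        f2 = fit_mixed(df, ModelSpec(fixed=["sqrt_rt"], random="genus_only"))
        assert f1.loglik >= f0.loglik - 1e-8
        assert f2.loglik >= f0.loglik - 1e-8


class TestSelectRandomStructure:
    def test_no_taxonomic_effect_chooses_none(self):
        chosen_none = 0
        for seed in range(25):
            df = oneway_frame(100 + seed, group_sd=0.0)
            chosen, _tests, _aic = select_random_structure(
                df, ModelSpec(fixed=["sqrt_rt"])
            )
            chosen_none += chosen == "none"
        assert chosen_none >= 21  # boundary-corrected alpha=0.05 per step

    def test_strong_genus_effect_detected(self):
        df = oneway_frame(7, group_sd=1.0, per_group=6)
        chosen, tests, aic = select_random_structure(df, ModelSpec(fixed=["sqrt_rt"]))
        assert chosen != "none"
        assert aic.loc[chosen, "aic"] <= aic.loc["none", "aic"]


class TestSelectFixedStructure:
    def test_noise_terms_dropped(self):
        dropped_all = 0
        for seed in range(20):
            df = oneway_frame(200 + seed, group_sd=0.5, slope=0.0)
            spec = ModelSpec(fixed=["contaminant_vs_rest", "sqrt_rt"])
            final, trail = select_fixed_structure(df, "genus_only", spec)
            dropped_all += final.fixed == []
        assert dropped_all >= 17  # ~alpha=0.05 per surviving term

    def test_real_slope_retained(self):
        df = oneway_frame(8, slope=0.25)
        final, _trail = select_fixed_structure(
            df, "genus_only", ModelSpec(fixed=["contaminant_vs_rest", "sqrt_rt"])
        )
        assert "sqrt_rt" in final.fixed

    def test_dropping_terms_never_increases_loglik(self):
        df = oneway_frame(9, slope=0.1)
        full = fit_mixed(df, ModelSpec(
            fixed=["contaminant_vs_rest", "sqrt_rt"], random="genus_only",
            estimation="ML"))
        reduced = fit_mixed(df, ModelSpec(
            fixed=["sqrt_rt"], random="genus_only", estimation="ML"))
        assert reduced.loglik <= full.loglik + 1e-8


class TestContrasts:
    def test_back_transform_identity(self):
        """exp(1.396) = 4.04: the log-scale mean back-transforms to ~4
        occupied seminatural habitats."""
        assert np.exp(1.396) == pytest.approx(4.04, abs=0.005)
        assert np.exp(0.0) == 1.0

    def test_contrast_detected_and_null_calibrated(self):
        rej = 0
        for seed in range(15):
            df = oneway_frame(300 + seed, group_sd=0.4)
            df["log_habitats_seminatural"] += 0.8 * df["contaminant_vs_rest"]
            fit = fit_mixed(df, ModelSpec(
                fixed=["contaminant_vs_rest"], random="genus_only"))
            out = seminatural_contrasts(fit)
            t = out["tests"]["contaminant_vs_rest"]
            rej += t.p_value < 0.05
            means = out["group_means"]["contaminant_vs_rest"]
            assert means[1] > means[0]
        assert rej == 15

    def test_null_contrast_lr_is_chi2(self):
        """With equal group means the contrast LR follows chi-square(1)
        (KS test over replicates)."""
        lrs = []
        for seed in range(60):
            df = oneway_frame(400 + seed, group_sd=0.3, per_group=5, n_groups=30)
            fit = fit_mixed(df, ModelSpec(
                fixed=["contaminant_vs_rest"], random="genus_only"))
            lrs.append(seminatural_contrasts(fit)["tests"]["contaminant_vs_rest"].statistic)
        assert stats.kstest(lrs, stats.chi2(1).cdf).pvalue > 0.01


class TestDiagnostics:
    def test_well_specified_model_flat_residuals(self):
        df = oneway_frame(
            10, n_groups=100, per_group=10, slope=0.6, group_sd=0.3, resid_sd=0.5
        )
        fit = fit_mixed(df, ModelSpec(fixed=["sqrt_rt"], random="genus_only"))
        d = diagnostics(fit)
        assert abs(d["check_regression_slope"]) < 0.05
        assert d["normal_quantile_correlation"] > 0.99

    def test_heavy_tails_lower_quantile_correlation(self):
        r = np.random.default_rng(11)
        df = oneway_frame(11, group_sd=0.0, resid_sd=1e-9)
        gauss = df.copy()
        gauss["log_habitats_seminatural"] += r.normal(0, 1, len(df))
        heavy = df.copy()
        heavy["log_habitats_seminatural"] += r.standard_t(1.5, len(df))
        fg = fit_mixed(gauss, ModelSpec(fixed=[], random="genus_only"))
        fh = fit_mixed(heavy, ModelSpec(fixed=[], random="genus_only"))
        assert (
            diagnostics(fh)["normal_quantile_correlation"]
            < diagnostics(fg)["normal_quantile_correlation"]
        )


class TestModelFrame:
    def test_zero_counts_dropped_from_log(self, small_synthetic):
        df = build_model_frame(small_synthetic)
        assert (df["log_habitats_seminatural"].dropna() >= 0).all()
        assert df["contaminant_vs_rest"].isin((0, 1)).all()

    def test_log1p_option(self, small_synthetic):
        df = build_model_frame(small_synthetic, zero_counts="log1p")
        assert df["log_habitats_seminatural"].notna().all()

    def test_stacked_habitat_frame(self, small_synthetic):
        """The long format pairs each species' total and seminatural counts
        under a two-level habitat_type factor, and the habitat-type effect
        is estimable (totals exceed seminatural counts by construction)."""
        from pathrise.range_models import build_stacked_habitat_frame

        long = build_stacked_habitat_frame(small_synthetic)
        assert set(long["habitat_type"]) == {"total", "seminatural"}
        assert len(long) == 2 * len(small_synthetic)
        fit = fit_mixed(long, ModelSpec(
            response="log_habitats", fixed=["habitat_type"], random="genus_only"))
        coef = fit.fixed_estimates
        name = [i for i in coef.index if "habitat_type" in i][0]
        assert coef.loc[name, "tvalue"] != 0
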