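"""Mixed-model fitting, AIC model comparison, stratified trend lines."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ppmr import dapstom_io, glmm_pipeline, size_structure, synthetic_data
from ppmr.glmm_pipeline import (
    ModelFitResult,
    ModelSpec,
    compare_linear_polynomial,
    fit_model,
    stratified_trendlines,
)


def _analysis(cfg):
    ds = synthetic_data.generate(cfg)
    matched = dapstom_io.build_matched_table(
        ds.stomachs, dapstom_io.EnvLayer(ds.sst), dapstom_io.EffortTable(ds.effort)
    )
    return glmm_pipeline.build_analysis_table(matched), ds


def test_slope_recovery_small(small_analysis, small_dataset):
    fit = fit_model(ModelSpec(with_effort=True), small_analysis)
    truth = small_dataset.truth["config"]
    assert fit.params["temperature"] == pytest.approx(
        truth["beta_T_ppmr"], abs=3 * fit.bse["temperature"]
    )
    assert fit.method == "mixed"
    assert set(fit.vcomp) == {"ices_rectangle", "season", "predator_species"}


def test_aic_identity_and_pseudo_r2(small_analysis):
    fit = fit_model(ModelSpec(), small_analysis)
    assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.llf, rel=1e-12)
    assert 0.0 <= fit.pseudo_r2 <= 1.0


def test_degenerate_constant_response_flagged(small_analysis):
    data = small_analysis.copy()
    data["log10_ppmr"] = 3.14
    fit = fit_model(ModelSpec(), data)
    assert fit.params["temperature"] == pytest.approx(0.0, abs=1e-10)
    assert any("degenerate" in n for n in fit.notes)
    assert fit.method == "ols"


def test_single_level_grouping_dropped(small_analysis):
    data = small_analysis.copy()
    data["season"] = "summer"
    fit = fit_model(ModelSpec(), data)
    assert "season" not in fit.vcomp
    assert any("season" in n for n in fit.notes)


def test_row_permutation_leaves_coefficients_unchanged(small_analysis):
    fit1 = fit_model(ModelSpec(), small_analysis)
    shuffled = small_analysis.sample(frac=1.0, random_state=123).reset_index(drop=True)
    shuffled.attrs = small_analysis.attrs
    fit2 = fit_model(ModelSpec(), shuffled)
    assert np.allclose(fit1.params, fit2.params, atol=1e-8)


def test_irrelevant_random_grouping_shifts_estimates_less_than_one_se():
    cfg = dataclasses.replace(
        synthetic_data.preset("paper_ppmr"), n_stomachs=1500, seed=21, sd_season=0.0
    )
    tab, _ = _analysis(cfg)
    with_season = fit_model(ModelSpec(), tab)
    without = fit_model(
        ModelSpec(random=("ices_rectangle", "predator_species")), tab
    )
    diff = abs(with_season.params["temperature"] - without.params["temperature"])
    assert diff < without.bse["temperature"]


# --- AIC linear-vs-polynomial selection


def _poly_frame(curvature, seed, n=400):
    rng = np.random.default_rng(seed)
    t = rng.uniform(4, 19, n)
    tc = t - t.mean()
    y = 2.0 + 0.03 * t + curvature * tc**2 + rng.normal(0, 0.25, n)
    return pd.DataFrame(
        {
            "log10_ppmr": y,
            "temperature": t,
            "temperature_sq_c": tc**2,
        }
    )


def test_quadratic_data_selects_quadratic():
    data = _poly_frame(curvature=0.01, seed=5)
    fit, record = compare_linear_polynomial(ModelSpec(random=()), data)
    assert record["selected"] == "quadratic"
    assert "temperature_sq_c" in fit.params.index
    assert record["aic_quadratic"] < record["aic_linear"]


def test_linear_data_selects_linear_at_the_theoretical_rate():
    """AIC keeps a superfluous quadratic term whenever its chi-square(1)
    deviance improvement exceeds 2, which happens with probability
    P(chi2_1 > 2) ~= 0.157; the observed selection count over 20 replicates
    must sit inside the binomial 3-sigma band around p = 0.843."""
    p = 0.8427  # P(chi2_1 < 2)
    n = 20
    wins = sum(
        compare_linear_polynomial(ModelSpec(random=()), _poly_frame(0.0, seed))[1][
            "selected"
        ]
        == "linear"
        for seed in range(n)
    )
    assert abs(wins / n - p) <= 3 * np.sqrt(p * (1 - p) / n)


def test_mixed_path_comparison_runs(small_analysis):
    fit, record = compare_linear_polynomial(ModelSpec(), small_analysis)
    assert record["selected"] in ("linear", "quadratic")
    assert np.isfinite(record["aic_linear"]) and np.isfinite(record["aic_quadratic"])


def test_aic_tie_prefers_linear():
    data = _poly_frame(0.0, seed=1)
    lin = fit_model(ModelSpec(random=()), data, reml=False)
    # a tie cannot be manufactured through real fits; check the decision rule
    # directly on the comparison record arithmetic
    _, record = compare_linear_polynomial(ModelSpec(random=()), data)
    if record["aic_quadratic"] >= record["aic_linear"]:
        assert record["selected"] == "linear"


# --- stratified trend lines


def _dummy_interaction_fit(b0, b_t, b_f, b_txf, mean=2.8, sd=0.25):
    names = ["Intercept", "temperature", "effort_std", "temperature:effort_std"]
    params = pd.Series([b0, b_t, b_f, b_txf], index=names)
    zeros = pd.Series(0.0, index=names)
    return ModelFitResult(
        spec=ModelSpec(with_effort=True),
        params=params,
        bse=zeros,
        tvalues=zeros,
        pvalues=zeros,
        df_resid=10.0,
        llf=0.0,
        aic=0.0,
        k_params=4,
        vcomp={},
        scale=1.0,
        n_obs=10,
        method="mixed",
        reml=True,
        converged=True,
        fitted=np.zeros(1),
        meta={"effort_log10_mean": mean, "effort_log10_sd": sd},
    )


def test_zero_interaction_gives_one_shared_slope():
    fit = _dummy_interaction_fit(2.0, 0.05, -0.1, 0.0)
    bins = size_structure.effort_terciles([100, 300, 500, 700, 900, 1100])
    lines = stratified_trendlines(fit, bins)
    assert lines["slope"].nunique() == 1
    assert lines["slope"].iloc[0] == pytest.approx(0.05)


def test_conditional_slope_is_linear_in_standardized_median():
    fit = _dummy_interaction_fit(2.0, 0.05, -0.1, 0.02)
    bins = size_structure.effort_terciles([100, 300, 500, 700, 900, 1100])
    lines = stratified_trendlines(fit, bins)
    for line in lines.itertuples():
        f = (np.log10(line.median_effort_hours) - 2.8) / 0.25
        assert line.slope == pytest.approx(0.05 + 0.02 * f, rel=1e-12)
        assert line.intercept == pytest.approx(2.0 - 0.1 * f, rel=1e-12)


def test_missing_interaction_refused(small_analysis):
    fit = fit_model(ModelSpec(), small_analysis)
    bins = size_structure.effort_terciles([1, 2, 3])
    with pytest.raises(ValueError, match="interaction"):
        stratified_trendlines(fit, bins)


def test_count_model_sign_pattern_flips_with_effort():
    """Prey count declining with temperature under low fishing but rising
    under high fishing is recovered by the interaction model."""
    cfg = synthetic_data.GeneratorConfig(
        n_stomachs=2500,
        beta_T_count=0.0,
        beta_TxF_count=0.02,
        mean_prey_per_stomach=4.0,
        seed=31,
    )
    tab, ds = _analysis(cfg)
    fit = fit_model(ModelSpec(response="log10_prey_count", with_effort=True), tab)
    bins = size_structure.effort_terciles(tab["effort_hours"])
    lines = stratified_trendlines(fit, bins).set_index("stratum")
    assert lines.loc["low", "slope"] < 0 < lines.loc["high", "slope"]


# --- nuisance covariates


def test_numeric_nuisance_covariate_binned_with_missing_rows_retained(small_analysis):
    rng = np.random.default_rng(0)
    data = small_analysis.copy()
    data["depth_m"] = rng.uniform(20, 200, len(data))
    data.loc[data.index[:100], "depth_m"] = np.nan
    data.attrs = small_analysis.attrs
    spec = ModelSpec(random=("ices_rectangle", "season", "predator_species", "depth_m"))
    fit = glmm_pipeline.fit_model(spec, data)
    assert fit.n_obs == len(data)  # missing-depth rows retained
    assert "depth_m_bin" in fit.vcomp
    assert any("decile-bin" in n for n in fit.notes)


def test_fixed_nuisance_mode_is_complete_case(small_analysis):
    rng = np.random.default_rng(0)
    data = small_analysis.copy()
    data["depth_m"] = rng.uniform(20, 200, len(data))
    data.loc[data.index[:100], "depth_m"] = np.nan
    data.attrs = small_analysis.attrs
    spec = ModelSpec(
        random=("ices_rectangle", "season", "predator_species", "depth_m"),
        nuisance_mode="fixed",
    )
    fit = glmm_pipeline.fit_model(spec, data)
    assert fit.n_obs == len(data) - 100
    assert "depth_m" in fit.params.index
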