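"""Linear mixed-effects models for the five diet responses.

Each response (log10 PPMR, log10 predator mass, log10 mean individual prey
mass, log10 prey count, log10 prey richness) is modelled against matched
temperature — optionally with standardized log10 fishing effort and the
temperature x effort interaction — with crossed Gaussian random intercepts
for ICES rectangle, season and predator species.  Crossed intercepts are
expressed through statsmodels' variance-component formulation on a single
grouping.

Fitting is by REML.  Linear-vs-quadratic comparison refits both candidates
by maximum likelihood, because REML likelihoods of models with different
fixed effects are not comparable; ties prefer the linear (parsimony).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelFitResult",
    "RESPONSES",
    "STANDARD_RANDOM",
    "build_analysis_table",
    "standardize_effort",
    "fit_model",
    "compare_linear_polynomial",
    "stratified_trendlines",
]

RESPONSES = (
    "log10_ppmr",
    "log10_predator_mass",
    "log10_prey_mass",
    "log10_prey_count",
    "log10_richness",
)
STANDARD_RANDOM = ("ices_rectangle", "season", "predator_species")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, fixed-effect structure, random groupings."""

    response: str = "log10_ppmr"
    with_effort: bool = False  # adds effort_std and temperature:effort_std
    quadratic: bool = False  # adds centred temperature squared
    fixed_extra: tuple[str, ...] = ()  # extra patsy terms (e.g. size-class)
    random: tuple[str, ...] = STANDARD_RANDOM
    # how numeric nuisance covariates listed in `random` enter the model:
    # "random_bins" -> decile-binned categorical random intercepts (rows with
    # a missing value share one "missing" level, so they are retained);
    # "fixed" -> ordinary fixed covariate (complete-case for those rows)
    nuisance_mode: str = "random_bins"

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(
                f"unknown response {self.response!r}; one of {RESPONSES}"
            )

    def formula(self) -> str:
        terms = ["temperature"]
        if self.quadratic:
            terms.append("temperature_sq_c")
        if self.with_effort:
            terms += ["effort_std", "temperature:effort_std"]
        terms += list(self.fixed_extra)
        return f"{self.response} ~ " + " + ".join(terms)


@dataclass
class ModelFitResult:
    """Fitted coefficients and diagnostics of one model."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: float
    llf: float
    aic: float
    k_params: int
    vcomp: dict
    scale: float
    n_obs: int
    method: str  # "mixed" or "ols"
    reml: bool
    converged: bool
    fitted: np.ndarray
    notes: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def pseudo_r2(self) -> float:
        """Conditional pseudo-R2: variance explained by fixed plus random
        terms over total (fixed + random + residual) variance."""
        var_fixed = float(np.var(self.fitted))
        var_rand = float(sum(self.vcomp.values()))
        denom = var_fixed + var_rand + self.scale
        return (var_fixed + var_rand) / denom if denom > 0 else float("nan")

    def predict_mean(self) -> float:
        return float(np.mean(self.fitted))


def standardize_effort(values: pd.Series) -> tuple[pd.Series, float, float]:
    """Centre/scale log10 effort hours; returns (standardized, mean, sd)."""
    log_eff = np.log10(values.astype(float))
    mean = float(np.nanmean(log_eff))
    sd = float(np.nanstd(log_eff, ddof=1))
    if not sd > 0:
        raise ValueError("effort has zero spread; cannot standardize")
    return (log_eff - mean) / sd, mean, sd


def build_analysis_table(matched_prey_df: pd.DataFrame) -> pd.DataFrame:
    """One row per stomach, analysis-ready.

    Input is a matched prey-row frame (``dapstom_io.build_matched_table``
    output).  Rows without SST are dropped (logged); rows without effort are
    kept with NaN effort columns — the temperature-only dataset — so the
    fishing subset is always a subset of it.
    """
    from ppmr.ppmr_core import compute_ppmr_table

    df = matched_prey_df
    n_nosst = int(df["sst_c"].isna().sum())
    if n_nosst:
        logger.warning("dropping %d prey row(s) without matched SST", n_nosst)
        df = df.loc[df["sst_c"].notna()]
    tab = compute_ppmr_table(df)
    tab = tab.rename(columns={"sst_c": "temperature"})
    tab["log10_predator_mass"] = np.log10(tab["predator_mass_g"])
    tab["log10_prey_mass"] = np.log10(tab["mean_prey_mass_g"])
    tab["log10_prey_count"] = np.log10(tab["n_prey"])
    tab["log10_richness"] = np.log10(tab["prey_richness"])
    tab["temperature_sq_c"] = (tab["temperature"] - tab["temperature"].mean()) ** 2
    if tab["effort_hours"].notna().any():
        eff_std, mean, sd = standardize_effort(tab["effort_hours"])
        tab["effort_std"] = eff_std
        tab.attrs["effort_log10_mean"] = mean
        tab.attrs["effort_log10_sd"] = sd
    else:
        tab["effort_std"] = np.nan
    return tab


def _spec_columns(spec: ModelSpec, data: pd.DataFrame) -> list[str]:
    cols = [spec.response, "temperature"]
    if spec.quadratic:
        cols.append("temperature_sq_c")
    if spec.with_effort:
        cols.append("effort_std")
    for term in spec.fixed_extra:
        for c in data.columns:
            if c in term:
                cols.append(c)
    return list(dict.fromkeys(cols))


def fit_model(spec: ModelSpec, data: pd.DataFrame, reml: bool = True) -> ModelFitResult:
    """REML fit of ``spec`` on an analysis table.

    Random groupings that collapse to fewer than two retained levels are
    dropped with a logged note.  A response with (near-)zero variance is fit
    by OLS and flagged degenerate.  Non-convergence is flagged on the
    result, never silently swallowed.
    """
    notes: list[str] = []
    if spec.nuisance_mode not in ("random_bins", "fixed"):
        raise ValueError(f"unknown nuisance_mode {spec.nuisance_mode!r}")
    numeric_random = [
        g
        for g in spec.random
        if g in data.columns and pd.api.types.is_numeric_dtype(data[g])
    ]
    cols = _spec_columns(spec, data) + [
        g for g in spec.random if g in data.columns and g not in numeric_random
    ]
    if spec.nuisance_mode == "fixed":
        cols += numeric_random  # complete-case for fixed nuisance covariates
    sub = data.dropna(subset=[c for c in cols if c in data.columns]).copy()
    if len(sub) == 0:
        raise ValueError("no complete rows for this model")

    fixed_nuisance: list[str] = []
    random = []
    for g in spec.random:
        if g not in sub.columns:
            notes.append(f"random grouping {g!r} absent from data; dropped")
            continue
        if g in numeric_random:
            if spec.nuisance_mode == "fixed":
                fixed_nuisance.append(g)
                notes.append(f"nuisance covariate {g!r} entered as a fixed effect (complete-case)")
                continue
            # a "random effect of a continuous covariate" is not estimable as
            # such; decile bins give it a categorical intercept structure
            binned = f"{g}_bin"
            sub[binned] = pd.qcut(sub[g], 10, duplicates="drop").astype(str)
            sub.loc[sub[g].isna(), binned] = "missing"
            notes.append(
                f"nuisance covariate {g!r} entered as decile-bin random "
                "intercepts; rows with missing values share one level"
            )
            g = binned
        if sub[g].nunique() < 2:
            notes.append(f"random grouping {g!r} has < 2 levels; dropped")
            logger.warning("dropping random grouping %r (<2 levels)", g)
            continue
        random.append(g)

    degenerate = float(np.std(sub[spec.response])) < 1e-12
    if degenerate:
        notes.append("response is (near-)constant; OLS fallback, flagged degenerate")

    formula = spec.formula()
    if fixed_nuisance:
        formula += " + " + " + ".join(fixed_nuisance)
    meta = {
        "formula": formula,
        "random": tuple(random),
        "effort_log10_mean": data.attrs.get("effort_log10_mean"),
        "effort_log10_sd": data.attrs.get("effort_log10_sd"),
    }

    if not random or degenerate:
        res = smf.ols(formula, data=sub).fit()
        k = len(res.params) + 1  # + residual variance
        return ModelFitResult(
            spec=spec,
            params=res.params,
            bse=res.bse,
            tvalues=res.tvalues,
            pvalues=res.pvalues,
            df_resid=float(res.df_resid),
            llf=float(res.llf),
            aic=2.0 * k - 2.0 * float(res.llf),
            k_params=k,
            vcomp={},
            scale=float(res.scale),
            n_obs=int(res.nobs),
            method="ols",
            reml=False,
            converged=True,
            fitted=np.asarray(res.fittedvalues),
            notes=notes,
            meta=meta,
        )

    sub["_group"] = 1
    vcf = {g: f"0 + C({g})" for g in random}
    model = smf.mixedlm(formula, sub, groups="_group", re_formula="0", vc_formula=vcf)
    # the sqrt parameterization of variance components flattens the gradient
    # near the boundary, where L-BFGS can stall at a poor optimum; fit with
    # two optimizers and keep the better (restricted) likelihood
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(reml=reml, method=["lbfgs"], maxiter=1000)
        res_p = model.fit(reml=reml, method=["powell"], maxiter=1000)
        if np.isfinite(res_p.llf) and (not np.isfinite(res.llf) or res_p.llf > res.llf):
            res = res_p
    for w in caught:
        if "Converge" in str(w.category.__name__) or "converge" in str(w.message).lower():
            notes.append(f"fitter warning: {w.message}")
    converged = bool(getattr(res, "converged", True))
    if not converged:
        notes.append("mixed model did not converge; estimates flagged")
        logger.warning("mixed model did not converge for %s", formula)

    fe_names = [p for p in res.params.index if p in res.fe_params.index]
    vc_names = list(model.exog_vc.names)  # statsmodels' own ordering
    vcomp = dict(zip(vc_names, np.asarray(res.vcomp, dtype=float)))
    k = len(fe_names) + len(vcomp) + 1
    llf = float(res.llf)
    return ModelFitResult(
        spec=spec,
        params=res.fe_params,
        bse=res.bse.loc[fe_names],
        tvalues=res.tvalues.loc[fe_names],
        pvalues=res.pvalues.loc[fe_names],
        df_resid=float(res.df_resid),
        llf=llf,
        aic=2.0 * k - 2.0 * llf,
        k_params=k,
        vcomp=vcomp,
        scale=float(res.scale),
        n_obs=int(res.nobs),
        method="mixed",
        reml=reml,
        converged=converged,
        fitted=np.asarray(res.fittedvalues),
        notes=notes,
        meta=meta,
    )


def compare_linear_polynomial(
    spec: ModelSpec, data: pd.DataFrame
) -> tuple[ModelFitResult, dict]:
    """AIC comparison of the linear model against one with an added
    quadratic temperature term (centred to decorrelate from the linear
    term).  Both candidates are fit by maximum likelihood; ties select the
    linear model (parsimony, logged)."""
    lin = fit_model(replace(spec, quadratic=False), data, reml=False)
    quad = fit_model(replace(spec, quadratic=True), data, reml=False)
    if quad.aic < lin.aic:
        selected, label = quad, "quadratic"
    else:
        selected, label = lin, "linear"
        if quad.aic == lin.aic:
            logger.info("AIC tie; linear preferred by parsimony")
    record = {
        "aic_linear": lin.aic,
        "aic_quadratic": quad.aic,
        "selected": label,
        "delta_aic": quad.aic - lin.aic,
    }
    return selected, record


def stratified_trendlines(fit: ModelFitResult, effort_bins) -> pd.DataFrame:
    """Per-effort-stratum (intercept, conditional temperature slope) lines.

    ``effort_bins`` carry raw-hour medians (``size_structure.effort_terciles``
    output); medians are mapped onto the model's standardized log10 effort
    scale using the standardization constants recorded at table build time.
    The conditional slope at a stratum with standardized effort f is
    ``beta_T + beta_TxF * f``.
    """
    if "temperature:effort_std" not in fit.params.index:
        raise ValueError("fit has no temperature x effort interaction term")
    mean = fit.meta.get("effort_log10_mean")
    sd = fit.meta.get("effort_log10_sd")
    if mean is None or sd is None:
        raise ValueError("fit carries no effort standardization constants")
    b0 = float(fit.params.get("Intercept", 0.0))
    b_t = float(fit.params["temperature"])
    b_f = float(fit.params.get("effort_std", 0.0))
    b_txf = float(fit.params["temperature:effort_std"])
    rows = []
    for b in effort_bins:
        f = (np.log10(b.median) - mean) / sd
        rows.append(
            {
                "stratum": b.label,
                "median_effort_hours": b.median,
                "effort_std": f,
                "intercept": b0 + b_f * f,
                "slope": b_t + b_txf * f,
            }
        )
    return pd.DataFrame(rows)
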