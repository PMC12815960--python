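"""Prey size classes, fishing-effort terciles, and the species-level
body-size response classification.

Size classes partition prey individual mass (grams) into small / medium /
large with half-open-upward boundaries; the shipped default cut points
(0.072 g and 1.25 g) follow the convention of size-structured diet studies
in the Northeast Atlantic, and an empirical mode recomputes them as
abundance terciles of the observed prey masses.

The species classification fits, per species, log10 individual body mass
against temperature (mixed model with a rectangle random intercept, falling
back to simple regression when the grouping collapses) and labels each
species *increase*, *decrease*, or *no change* by slope sign and a
two-sided test at ``alpha``; categories are then aggregated as percent of
species and percent of total biomass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = [
    "SizeClassScheme",
    "PAPER_DEFAULT_SCHEME",
    "TercileBin",
    "SpeciesResponseTable",
    "assign_size_class",
    "assign_size_classes",
    "empirical_tercile_scheme",
    "effort_terciles",
    "size_class_table",
    "classify_species_responses",
]


@dataclass(frozen=True)
class SizeClassScheme:
    """Two cut points (grams) splitting (0, inf) into small/medium/large."""

    cut1: float
    cut2: float
    provenance: str = "paper-default"

    def __post_init__(self) -> None:
        if not 0 < self.cut1 < self.cut2:
            raise ValueError("cut points must satisfy 0 < cut1 < cut2")


PAPER_DEFAULT_SCHEME = SizeClassScheme(0.072, 1.25, "paper-default")


def assign_size_class(mass: float, scheme: SizeClassScheme = PAPER_DEFAULT_SCHEME) -> str:
    """small if mass < cut1, medium if cut1 <= mass < cut2, else large."""
    if not mass > 0:
        raise ValueError(f"mass must be > 0, got {mass}")
    if mass < scheme.cut1:
        return "small"
    if mass < scheme.cut2:
        return "medium"
    return "large"


def assign_size_classes(
    masses, scheme: SizeClassScheme = PAPER_DEFAULT_SCHEME
) -> np.ndarray:
    masses = np.asarray(masses, dtype=float)
    if (masses <= 0).any():
        raise ValueError("masses must be > 0")
    out = np.where(masses < scheme.cut1, "small", np.where(masses < scheme.cut2, "medium", "large"))
    return out


def empirical_tercile_scheme(masses, counts=None) -> SizeClassScheme:
    """Cut points at the abundance terciles of prey individual mass."""
    masses = np.asarray(masses, dtype=float)
    if counts is None:
        counts = np.ones_like(masses)
    rep = np.repeat(masses, np.asarray(counts, dtype=int))
    c1, c2 = np.quantile(rep, [1 / 3, 2 / 3])
    return SizeClassScheme(float(c1), float(c2), "empirical-terciles")


@dataclass(frozen=True)
class TercileBin:
    label: str
    count: int
    low: float
    high: float
    median: float


def effort_terciles(efforts) -> list[TercileBin]:
    """Split effort values into three equal-count bins (remainders go to the
    lower bins) and report each bin's range and median."""
    values = np.sort(np.asarray(list(efforts), dtype=float))
    n = len(values)
    if n < 3:
        raise ValueError("need at least 3 effort values for terciles")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    if values[0] == values[-1]:
        logger.warning("all effort values equal; terciles are degenerate")
    bins = []
    start = 0
    for label, size in zip(("low", "medium", "high"), sizes):
        chunk = values[start : start + size]
        bins.append(
            TercileBin(
                label=label,
                count=size,
                low=float(chunk[0]),
                high=float(chunk[-1]),
                median=float(np.median(chunk)),
            )
        )
        start += size
    return bins


def size_class_table(
    matched_prey_df: pd.DataFrame, scheme: SizeClassScheme = PAPER_DEFAULT_SCHEME
) -> pd.DataFrame:
    """Stomach x size-class aggregation for the prey count and richness
    models: per (stomach, size class), total prey abundance and taxon
    richness with log10 transforms; empty cells are absent, not zero-filled.
    """
    df = matched_prey_df.copy()
    df["size_class"] = assign_size_classes(df["prey_indiv_mass_g"], scheme)
    group_cols = ["stomach_id", "size_class"]
    keep = [
        c
        for c in [
            "predator_species",
            "predator_mass_g",
            "ices_rectangle",
            "season",
            "sst_c",
            "effort_hours",
            "year",
            "month",
        ]
        if c in df.columns
    ]
    agg = (
        df.groupby(group_cols, sort=False)
        .agg(
            n_prey=("prey_count", "sum"),
            prey_richness=("prey_taxon", "nunique"),
            **{c: (c, "first") for c in keep},
        )
        .reset_index()
    )
    agg = agg.rename(columns={"sst_c": "temperature"})
    agg["log10_prey_count"] = np.log10(agg["n_prey"])
    agg["log10_richness"] = np.log10(agg["prey_richness"])
    return agg


@dataclass
class SpeciesResponseTable:
    """Per-species slopes plus the category summary.

    ``detail`` has one row per analysed species (slope, p, biomass,
    category, fit method); ``summary`` has one row per category with
    percent-of-species and percent-of-biomass; ``excluded`` lists species
    below the minimum-observation threshold.
    """

    detail: pd.DataFrame
    summary: pd.DataFrame
    excluded: list[str]
    alpha: float


def _fit_species_slope(grp: pd.DataFrame, mass_col: str) -> tuple[float, float, str]:
    """(slope, p, method) of log10 mass vs temperature for one species,
    with a rectangle random intercept when estimable."""
    d = grp[[mass_col, "sst_c"] + (["ices_rectangle"] if "ices_rectangle" in grp else [])].copy()
    d["log10_mass"] = np.log10(d[mass_col])
    use_mixed = "ices_rectangle" in d.columns and d["ices_rectangle"].nunique() >= 2
    if use_mixed:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm(
                    "log10_mass ~ sst_c", d, groups=d["ices_rectangle"]
                ).fit(reml=True, method=["lbfgs", "bfgs"])
            return float(res.fe_params["sst_c"]), float(res.pvalues["sst_c"]), "mixed"
        except Exception as exc:  # singular fits on tiny groups
            logger.warning("mixed fit failed (%s); falling back to OLS", exc)
    res = smf.ols("log10_mass ~ sst_c", d).fit()
    return float(res.params["sst_c"]), float(res.pvalues["sst_c"]), "ols"


def classify_species_responses(
    data: pd.DataFrame,
    alpha: float = 0.05,
    min_obs: int = 30,
    species_col: str = "prey_taxon",
    mass_col: str = "prey_indiv_mass_g",
    count_col: str = "prey_count",
) -> SpeciesResponseTable:
    """Classify each species' individual-body-mass response to temperature.

    ``data`` must carry ``species_col``, ``mass_col``, ``sst_c`` and
    (optionally) ``ices_rectangle`` and ``count_col``.  Species with fewer
    than ``min_obs`` rows are excluded and listed.  Biomass per species is
    the summed count x mass.
    """
    if species_col not in data.columns:
        raise ValueError(f"no species column {species_col!r}")
    rows = []
    excluded: list[str] = []
    counts = (
        data[count_col].astype(float) if count_col in data.columns else pd.Series(1.0, index=data.index)
    )
    biomass_all = counts * data[mass_col].astype(float)
    for sp, grp in data.groupby(species_col, sort=True):
        if len(grp) < min_obs:
            excluded.append(str(sp))
            continue
        slope, p, method = _fit_species_slope(grp, mass_col)
        if p >= alpha or not np.isfinite(p):
            cat = "no change"
        else:
            cat = "increase" if slope > 0 else "decrease"
        rows.append(
            {
                "species": str(sp),
                "n_obs": len(grp),
                "slope": slope,
                "p_value": p,
                "biomass_g": float(biomass_all.loc[grp.index].sum()),
                "category": cat,
                "method": method,
            }
        )
    if not rows:
        raise ValueError("no species met the minimum-observation threshold")
    detail = pd.DataFrame(rows)
    total_b = detail["biomass_g"].sum()
    summary_rows = []
    for cat in ("no change", "increase", "decrease"):
        sel = detail["category"] == cat
        summary_rows.append(
            {
                "category": cat,
                "pct_species": 100.0 * sel.sum() / len(detail),
                "pct_biomass": 100.0 * detail.loc[sel, "biomass_g"].sum() / total_b,
            }
        )
    summary = pd.DataFrame(summary_rows)
    return SpeciesResponseTable(detail=detail, summary=summary, excluded=excluded, alpha=alpha)
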