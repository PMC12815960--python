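"""The biomass-weighted predator-prey mass ratio and the percent-change
arithmetic used to report temperature effects.

For one stomach the statistic is

    PPMR = M_pred / mean_prey_mass,
    mean_prey_mass = (1/n) * sum over prey individuals of their body mass
                   = sum_k(count_k * mass_k) / sum_k(count_k)

with n the total abundance of prey in the stomach — the abundance-weighted
arithmetic mean of prey individual mass.  PPMR is computed per predator
individual; stomachs with no (usable) prey yield no observation.

Fitted temperature slopes live on the log10 scale; a slope ``b`` per degC
back-transforms to a percent change in PPMR of ``(10**b - 1) * 100`` per
degC, compounding to ``(10**(b*dT) - 1) * 100`` across a gradient of span
``dT``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ppmr.dapstom_io import StomachRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PPMRObservation",
    "compute_ppmr",
    "compute_ppmr_table",
    "geometric_mean_prey_mass",
    "biomass_weighted_mean_prey_mass",
    "pct_change_per_degree",
    "pct_change_over_gradient",
    "gradient_span_for_total",
]


@dataclass(frozen=True)
class PPMRObservation:
    """Per-stomach PPMR summary."""

    stomach_id: str
    ppmr: float
    log10_ppmr: float
    n_prey: int
    mean_prey_mass: float
    prey_richness: int


def compute_ppmr(record: StomachRecord) -> PPMRObservation | None:
    """Biomass-weighted PPMR for one predator stomach.

    Returns None for an empty stomach (excluded, not an error) and for a
    stomach carrying any non-positive mass (refused and logged; invalid rows
    normally never get this far because readers validate them).
    """
    if not record.prey:
        return None
    if record.predator_mass <= 0 or any(p.indiv_mass <= 0 for p in record.prey):
        logger.warning("stomach %s refused: non-positive mass", record.stomach_id)
        return None
    n = sum(p.count for p in record.prey)
    mean_prey = sum(p.count * p.indiv_mass for p in record.prey) / n
    ppmr = record.predator_mass / mean_prey
    return PPMRObservation(
        stomach_id=record.stomach_id,
        ppmr=ppmr,
        log10_ppmr=math.log10(ppmr),
        n_prey=n,
        mean_prey_mass=mean_prey,
        prey_richness=len({p.taxon for p in record.prey}),
    )


def compute_ppmr_table(prey_df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-stomach PPMR over a prey-row frame.

    Returns one row per stomach with ``n_prey``, ``prey_richness``,
    ``mean_prey_mass_g``, ``ppmr`` and ``log10_ppmr`` alongside the
    stomach-level attributes (predator species/mass, position, date, and any
    matched covariate columns present in the input).
    """
    df = prey_df
    w = df["prey_count"].to_numpy(dtype=float)
    m = df["prey_indiv_mass_g"].to_numpy(dtype=float)
    agg = (
        df.assign(_wm=w * m, _w=w)
        .groupby("stomach_id", sort=False)
        .agg(
            n_prey=("_w", "sum"),
            _wm=("_wm", "sum"),
            prey_richness=("prey_taxon", "nunique"),
        )
        .reset_index()
    )
    agg["mean_prey_mass_g"] = agg["_wm"] / agg["n_prey"]
    agg = agg.drop(columns="_wm")

    stomach_cols = [
        c
        for c in df.columns
        if c
        not in {"prey_taxon", "prey_family", "prey_count", "prey_indiv_mass_g"}
        and c != "stomach_id"
    ]
    heads = df.groupby("stomach_id", sort=False)[stomach_cols].first().reset_index()
    out = heads.merge(agg, on="stomach_id")
    out["ppmr"] = out["predator_mass_g"] / out["mean_prey_mass_g"]
    out["log10_ppmr"] = np.log10(out["ppmr"])
    return out


def geometric_mean_prey_mass(counts, masses) -> float:
    """Abundance-weighted geometric mean prey mass — an alternative PPMR
    denominator convention, never the default."""
    counts = np.asarray(counts, dtype=float)
    masses = np.asarray(masses, dtype=float)
    return float(np.exp(np.sum(counts * np.log(masses)) / np.sum(counts)))


def biomass_weighted_mean_prey_mass(counts, masses) -> float:
    """Biomass-weighted (not abundance-weighted) mean prey mass — an
    alternative denominator convention, never the default."""
    counts = np.asarray(counts, dtype=float)
    masses = np.asarray(masses, dtype=float)
    return float(np.sum(counts * masses**2) / np.sum(counts * masses))


def pct_change_per_degree(b: float) -> float:
    """Percent change per 1 degC implied by a log10-scale slope ``b``."""
    return (10.0**b - 1.0) * 100.0


def pct_change_over_gradient(b: float, delta_t: float) -> float:
    """Percent change across a temperature span ``delta_t`` (degC) implied by
    a log10-scale slope ``b``; compounds ``pct_change_per_degree``."""
    if not delta_t > 0:
        raise ValueError("temperature span must be > 0")
    return (10.0 ** (b * delta_t) - 1.0) * 100.0


def gradient_span_for_total(per_degree_pct: float, total_pct: float) -> float:
    """Span dT (degC) over which a per-degree percent change compounds to a
    total percent change: solves (1 + per/100)**dT = 1 + total/100."""
    return math.log1p(total_pct / 100.0) / math.log1p(per_degree_pct / 100.0)
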