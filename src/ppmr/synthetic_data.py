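"""Synthetic stomach-content, SST, and fishing-effort tables with known
ground truth.

The generator emulates the three tables a DAPSTOM-style PPMR study joins
(prey rows per stomach; gridded monthly SST; annual effort per ICES
rectangle) under an explicit true model, so every downstream stage has a
recovery-based test:

* rectangles sit on a latitudinal temperature gradient spanning
  ``temp_range`` plus a seasonal cycle; the SST table is written so the
  one-month-lag matching rule reproduces exactly the temperature the truth
  used;
* annual effort per rectangle is log-normal, calibrated so its terciles
  resemble the effort strata of heavily fished shelf seas (roughly
  45-566 / 576-878 / 903-3479 h per year);
* true log10 PPMR per stomach is linear in matched temperature, in
  standardized log10 effort, and in their product, plus Gaussian random
  intercepts for rectangle, season and predator species and a residual;
* predator mass has its own log10-linear temperature model with a species
  intercept; the stomach's prey items are then sampled and rescaled so the
  abundance-weighted mean prey mass makes the PPMR identity hold exactly —
  the generative model is the exact inverse of the per-stomach statistic.

Because mean prey mass is predator mass divided by PPMR, the implied
log10 individual prey mass model has intercept ``beta0_pred - beta0_ppmr``
and slope ``beta_T_pred - beta_T_ppmr``; presets are calibrated through
that identity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ppmr.dapstom_io import rectangle_from_code, season_from_month

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate",
    "preset",
    "PRESET_NAMES",
    "generate_species_table",
    "TERCILE_MEDIAN_Z",
]

# |median of the outer terciles of a standard normal| = |Phi^-1(1/6)|;
# used to convert per-stratum published slopes into interaction coefficients.
TERCILE_MEDIAN_Z = float(-stats.norm.ppf(1.0 / 6.0))

_SEASONS = ["winter", "spring", "summer", "autumn"]


@dataclass
class GeneratorConfig:
    """True effect sizes, variance components and design of the simulation.

    All slopes/intercepts are on the log10 scale; temperature in degC;
    effort enters the true model as centred/scaled log10 hours.
    """

    n_stomachs: int = 5000
    temp_range: tuple[float, float] = (4.0, 19.0)
    seasonal_amp: float = 1.5  # degC amplitude of the within-year SST cycle

    # log10 PPMR true model
    beta0_ppmr: float = 2.2
    beta_T_ppmr: float = 0.041
    beta_F_ppmr: float = 0.0  # main effect of standardized log10 effort
    beta_TxF_ppmr: float = 0.0  # interaction per (degC * standardized effort)

    # log10 predator mass true model
    beta0_pred: float = 2.3
    beta_T_pred: float = 0.0029

    # variance components (log10 scale) of the PPMR model
    sd_rect: float = 0.05
    sd_season: float = 0.05
    sd_species: float = 0.15
    sd_resid: float = 0.3
    # predator-mass model noise
    sd_species_pred: float = 0.25
    sd_resid_pred: float = 0.2
    # log10 dispersion of individual prey masses within a stomach
    prey_item_sd: float = 0.2

    # prey-rows-per-stomach model: mean rows = 10**(log10(mean_prey_per_stomach)
    # + beta_T_count*T + beta_TxF_count*T*F), floored at one row
    mean_prey_per_stomach: float = 3.0
    beta_T_count: float = 0.0
    beta_TxF_count: float = 0.0

    n_species: int = 20
    n_prey_taxa: int = 40
    n_prey_families: int = 10
    n_rectangles: int = 40
    year_range: tuple[int, int] = (2005, 2010)

    # log-normal annual effort, natural-log parameters of hours/year
    effort_mu_log: float = 6.572
    effort_sigma_log: float = 0.543
    # fraction of rectangle-years with an effort record (holes if < 1)
    effort_coverage: float = 1.0

    seed: int = 1

    def __post_init__(self) -> None:
        sds = [
            self.sd_rect,
            self.sd_season,
            self.sd_species,
            self.sd_resid,
            self.sd_species_pred,
            self.sd_resid_pred,
            self.prey_item_sd,
        ]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be >= 0")
        if not self.temp_range[1] > self.temp_range[0]:
            raise ValueError("temp_range must be nondegenerate (min < max)")
        for name in ("n_stomachs", "n_species", "n_prey_taxa", "n_prey_families", "n_rectangles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.effort_coverage <= 1.0:
            raise ValueError("effort_coverage must be in [0, 1]")
        if self.mean_prey_per_stomach < 1:
            raise ValueError("mean_prey_per_stomach must be >= 1")

    # the prey-mass model implied by the predator-mass and PPMR models
    @property
    def beta0_prey(self) -> float:
        return self.beta0_pred - self.beta0_ppmr

    @property
    def beta_T_prey(self) -> float:
        return self.beta_T_pred - self.beta_T_ppmr


@dataclass
class SyntheticDataset:
    stomachs: pd.DataFrame  # one row per prey item (stomach-table layout)
    sst: pd.DataFrame  # year, month, lat, lon, sst_c
    effort: pd.DataFrame  # year, ices_rectangle, effort_hours
    truth: dict = field(default_factory=dict)


def _rectangle_codes(n: int) -> list[str]:
    """n ICES rectangles in two adjacent 1-deg columns (F3/F4, i.e. 3-5 degE)
    climbing north from 50 degN in 0.5-deg rows."""
    codes = []
    band0 = int((50.0 - 36.0) / 0.5)  # row index for 50.0N
    for i in range(n):
        row = band0 + i // 2 + 1  # printed row number = band + 1
        col = "F3" if i % 2 == 0 else "F4"
        codes.append(f"{row:02d}{col}")
    return codes


def _sst_value(base: float, amp: float, month: int) -> float:
    return base + amp * np.cos(2.0 * np.pi * (month - 8) / 12.0)


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw the three tables plus a truth record under ``config``.

    Deterministic in (config, config.seed): identical configs give
    identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_stomachs
    y0, y1 = config.year_range
    years = list(range(y0, y1 + 1))

    codes = _rectangle_codes(config.n_rectangles)
    rects = [rectangle_from_code(c) for c in codes]
    rect_lat0 = np.array([36.0 + 0.5 * r.lat_band for r in rects])
    rect_lon0 = np.array([-44.0 + r.lon_band for r in rects])

    # latitudinal gradient: southernmost rectangles warmest; the seasonal
    # cycle fills the rest of temp_range
    tmin, tmax = config.temp_range
    amp = config.seasonal_amp
    frac = (rect_lat0 - rect_lat0.min()) / max(rect_lat0.max() - rect_lat0.min(), 0.5)
    base_t = (tmax - amp) - ((tmax - amp) - (tmin + amp)) * frac

    # --- SST grid: one 0.5 x 1 deg cell per rectangle, all months incl. the
    # December before the first sampling year (the lag rule needs it)
    sst_rows = []
    for ri, code in enumerate(codes):
        for year in range(y0 - 1, y1 + 1):
            for month in range(1, 13):
                sst_rows.append(
                    (
                        year,
                        month,
                        rect_lat0[ri],
                        rect_lon0[ri],
                        round(_sst_value(base_t[ri], amp, month), 4),
                    )
                )
    sst = pd.DataFrame(sst_rows, columns=["year", "month", "lat", "lon", "sst_c"])

    # --- effort: log-normal hours per rectangle-year
    eff_rows = []
    for code in codes:
        for year in years:
            if config.effort_coverage < 1.0 and rng.random() > config.effort_coverage:
                continue
            hours = float(rng.lognormal(config.effort_mu_log, config.effort_sigma_log))
            eff_rows.append((year, code, round(hours, 2)))
    effort = pd.DataFrame(eff_rows, columns=["year", "ices_rectangle", "effort_hours"])
    effort_lookup = {(r.year, r.ices_rectangle): r.effort_hours for r in effort.itertuples()}

    # --- stomach-level design
    rect_idx = rng.integers(0, config.n_rectangles, n)
    year_arr = rng.integers(y0, y1 + 1, n)
    month_arr = rng.integers(1, 13, n)
    # keep positions strictly inside the rectangle so the 4-dp rounding of
    # written coordinates can never cross a cell boundary
    lat = rect_lat0[rect_idx] + rng.uniform(0.001, 0.499, n)
    lon = rect_lon0[rect_idx] + rng.uniform(0.001, 0.999, n)
    species_idx = rng.integers(0, config.n_species, n)
    season_arr = np.array([season_from_month(m) for m in month_arr])
    season_idx = np.array([_SEASONS.index(s) for s in season_arr])

    # matched temperature = previous-month SST of the stomach's cell
    prev_month = np.where(month_arr == 1, 12, month_arr - 1)
    temp = np.array(
        [_sst_value(base_t[r], amp, m) for r, m in zip(rect_idx, prev_month)]
    )
    temp = np.round(temp, 4)  # match the precision written to the SST table

    eff_hours = np.array(
        [
            effort_lookup.get((int(y), codes[r]), np.nan)
            for y, r in zip(year_arr, rect_idx)
        ]
    )
    log_eff = np.log10(eff_hours)
    eff_mean = float(np.nanmean(log_eff))
    eff_sd = float(np.nanstd(log_eff, ddof=1))
    f_std = (log_eff - eff_mean) / eff_sd
    f_model = np.where(np.isnan(f_std), 0.0, f_std)  # unmatched: neutral effort

    u_rect = rng.normal(0.0, config.sd_rect, config.n_rectangles)
    u_season = rng.normal(0.0, config.sd_season, 4)
    u_species = rng.normal(0.0, config.sd_species, config.n_species)
    v_species = rng.normal(0.0, config.sd_species_pred, config.n_species)

    eta_ppmr = (
        config.beta0_ppmr
        + config.beta_T_ppmr * temp
        + config.beta_F_ppmr * f_model
        + config.beta_TxF_ppmr * temp * f_model
        + u_rect[rect_idx]
        + u_season[season_idx]
        + u_species[species_idx]
        + rng.normal(0.0, config.sd_resid, n)
    )
    log10_mpred = (
        config.beta0_pred
        + config.beta_T_pred * temp
        + v_species[species_idx]
        + rng.normal(0.0, config.sd_resid_pred, n)
    )
    log10_target_prey = log10_mpred - eta_ppmr

    # prey rows per stomach
    log_mu = (
        np.log10(config.mean_prey_per_stomach)
        + config.beta_T_count * temp
        + config.beta_TxF_count * temp * f_model
    )
    mu_rows = np.maximum(10.0**log_mu - 1.0, 0.0)
    n_rows = 1 + rng.poisson(mu_rows)

    species_names = [f"pred_{i:02d}" for i in range(config.n_species)]
    taxa_names = [f"prey_{i:02d}" for i in range(config.n_prey_taxa)]
    family_of = {
        t: f"fam_{i % config.n_prey_families:02d}" for i, t in enumerate(taxa_names)
    }

    rows = []
    for i in range(n):
        k = int(n_rows[i])
        taxa = rng.integers(0, config.n_prey_taxa, k)
        counts = 1 + rng.poisson(0.7, k)
        rel = 10.0 ** rng.normal(0.0, config.prey_item_sd, k)
        wmean = float(np.sum(counts * rel) / np.sum(counts))
        masses = rel * (10.0 ** log10_target_prey[i]) / wmean
        sid = f"s{i:06d}"
        hid = f"h_{codes[rect_idx[i]]}_{year_arr[i]}_{month_arr[i]:02d}"
        for t, c, m in zip(taxa, counts, masses):
            rows.append(
                (
                    sid,
                    hid,
                    species_names[species_idx[i]],
                    round(10.0 ** log10_mpred[i], 6),
                    taxa_names[t],
                    family_of[taxa_names[t]],
                    int(c),
                    float(m),
                    round(lat[i], 4),
                    round(lon[i], 4),
                    int(year_arr[i]),
                    int(month_arr[i]),
                )
            )
    stomachs = pd.DataFrame(
        rows,
        columns=[
            "stomach_id",
            "haul_id",
            "predator_species",
            "predator_mass_g",
            "prey_taxon",
            "prey_family",
            "prey_count",
            "prey_indiv_mass_g",
            "lat",
            "lon",
            "year",
            "month",
        ],
    )

    z = TERCILE_MEDIAN_Z
    truth = {
        "config": dataclasses.asdict(config),
        "beta0_prey": config.beta0_prey,
        "beta_T_prey": config.beta_T_prey,
        "effort_log10_mean": eff_mean,
        "effort_log10_sd": eff_sd,
        "rect_codes": codes,
        "rect_base_temp": base_t.tolist(),
        "u_rect": dict(zip(codes, u_rect.tolist())),
        "u_season": dict(zip(_SEASONS, u_season.tolist())),
        "u_species": dict(zip(species_names, u_species.tolist())),
        "v_species_pred": dict(zip(species_names, v_species.tolist())),
        # conditional temperature slopes of log10 PPMR at the population
        # tercile medians of standardized log effort
        "slope_low_effort": config.beta_T_ppmr - config.beta_TxF_ppmr * z,
        "slope_high_effort": config.beta_T_ppmr + config.beta_TxF_ppmr * z,
    }
    return SyntheticDataset(stomachs=stomachs, sst=sst, effort=effort, truth=truth)


PRESET_NAMES = ("paper_ppmr", "paper_interaction", "paper_preymass", "paper_predmass")


def preset(name: str) -> GeneratorConfig:
    """Calibrated generator configurations.

    * ``paper_ppmr`` — log10 PPMR vs temperature with intercept 2.2 and
      slope 0.041 per degC, no fishing terms;
    * ``paper_interaction`` — temperature x effort interaction calibrated so
      the conditional slope is 0.03 at the low effort-tercile median and
      0.10 at the high-tercile median (with matching per-stratum intercepts
      2.2 and 1.7);
    * ``paper_preymass`` — implied log10 individual prey mass model with
      intercept -0.53 and slope -0.0012 per degC;
    * ``paper_predmass`` — log10 predator mass model with intercept 2.3 and
      slope 0.0029 per degC.

    All presets share the 4-19 degC gradient, moderate variance components
    and seed 1.
    """
    z = TERCILE_MEDIAN_Z
    if name == "paper_ppmr":
        return GeneratorConfig(beta0_ppmr=2.2, beta_T_ppmr=0.041)
    if name == "paper_interaction":
        low_i, low_s = 2.2, 0.03
        high_i, high_s = 1.7, 0.1
        return GeneratorConfig(
            beta0_ppmr=(low_i + high_i) / 2.0,
            beta_T_ppmr=(low_s + high_s) / 2.0,
            beta_F_ppmr=(high_i - low_i) / (2.0 * z),
            beta_TxF_ppmr=(high_s - low_s) / (2.0 * z),
        )
    if name == "paper_preymass":
        # prey model = predator model minus PPMR model
        return GeneratorConfig(
            beta0_pred=2.3,
            beta_T_pred=0.0029,
            beta0_ppmr=2.3 - (-0.53),
            beta_T_ppmr=0.0029 - (-0.0012),
        )
    if name == "paper_predmass":
        return GeneratorConfig(beta0_pred=2.3, beta_T_pred=0.0029)
    raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")


def generate_species_table(
    n_species: int,
    slopes,
    n_obs_per_species: int = 60,
    n_rectangles: int = 15,
    temp_range: tuple[float, float] = (4.0, 19.0),
    sd_rect: float = 0.05,
    sd_resid: float = 0.2,
    base_mass_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-species body-mass observations with known temperature slopes, for
    testing the species-response classifier.

    ``slopes`` is a scalar or length-``n_species`` array of true log10-mass
    slopes per degC.  Returns a prey-row-style frame with columns
    ``prey_taxon``, ``prey_family``, ``prey_count`` (=1),
    ``prey_indiv_mass_g``, ``sst_c`` and ``ices_rectangle``, plus a
    ``true_slope`` column.
    """
    rng = np.random.default_rng(seed)
    slopes = np.broadcast_to(np.asarray(slopes, dtype=float), (n_species,))
    codes = _rectangle_codes(n_rectangles)
    u_rect = rng.normal(0.0, sd_rect, n_rectangles)
    base = rng.normal(-0.5, base_mass_sd, n_species)
    rows = []
    for s in range(n_species):
        temps = rng.uniform(*temp_range, n_obs_per_species)
        ridx = rng.integers(0, n_rectangles, n_obs_per_species)
        logm = (
            base[s]
            + slopes[s] * temps
            + u_rect[ridx]
            + rng.normal(0.0, sd_resid, n_obs_per_species)
        )
        for t, r, lm in zip(temps, ridx, logm):
            rows.append(
                (
                    f"sp_{s:03d}",
                    f"fam_{s % 10:02d}",
                    1,
                    10.0**lm,
                    round(float(t), 4),
                    codes[r],
                    slopes[s],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "prey_taxon",
            "prey_family",
            "prey_count",
            "prey_indiv_mass_g",
            "sst_c",
            "ices_rectangle",
            "true_slope",
        ],
    )
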