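"""Stomach-content data model, readers, ICES rectangle geometry, and
spatiotemporal matching of stomachs to sea-surface temperature and
commercial fishing effort.

The data model mirrors DAPSTOM-style diet records: one predator stomach
holds a list of prey items, each with a taxon, an abundance (count) and an
individual wet weight in grams.  Environmental covariates are joined by two
rules used throughout the pipeline:

* temperature — the monthly mean SST of the grid cell containing the
  sampling position, for the *previous* calendar month (a one-month lag, so
  a stomach sampled May 1992 is matched to April 1992; January records use
  December of the preceding year);
* fishing effort — annual fishing hours for the ICES statistical rectangle
  (0.5 deg latitude x 1 deg longitude) containing the sampling position,
  matched on year.

A record that cannot be matched is flagged, never silently zero-filled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PreyItem",
    "StomachRecord",
    "RectangleID",
    "EnvLayer",
    "EffortTable",
    "assign_rectangle",
    "rectangle_from_code",
    "rectangle_center",
    "season_from_month",
    "previous_month",
    "read_stomach_table",
    "read_prey_frame",
    "stomach_frame",
    "match_temperature",
    "match_effort",
    "build_matched_table",
    "STOMACH_COLUMNS",
    "OPTIONAL_COVARIATE_COLUMNS",
]

# ICES statistical-rectangle grid: 0.5 deg latitude rows numbered "01", "02",
# ... northward from 36 deg N; 1 deg longitude columns lettered westward from
# 44 deg W.  Letter "A" spans only 44W-40W (codes A0-A3); letters B..M (I is
# skipped) each span 10 deg with a trailing digit per 1 deg column.
ICES_LAT_ORIGIN = 36.0
ICES_LON_ORIGIN = -44.0
_WIDE_LETTERS = "BCDEFGHJKLM"
_MAX_LON_BAND = 4 + 10 * len(_WIDE_LETTERS)  # exclusive upper band index

STOMACH_COLUMNS = [
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
]
OPTIONAL_COVARIATE_COLUMNS = ["chlorophyll_ugl", "salinity_psu", "depth_m"]


@dataclass(frozen=True)
class PreyItem:
    """One prey row in a stomach: ``count`` individuals of ``taxon``, each of
    individual wet weight ``indiv_mass`` grams."""

    taxon: str
    family: str
    count: int
    indiv_mass: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"prey count must be >= 1, got {self.count}")
        if not self.indiv_mass > 0:
            raise ValueError(f"prey mass must be > 0, got {self.indiv_mass}")


@dataclass
class StomachRecord:
    """One predator individual and its stomach contents — the unit of PPMR."""

    stomach_id: str
    predator_species: str
    predator_mass: float  # wet weight, grams
    lat: float
    lon: float
    year: int
    month: int
    prey: list[PreyItem] = field(default_factory=list)
    haul_id: str = ""

    def __post_init__(self) -> None:
        if not self.predator_mass > 0:
            raise ValueError("predator mass must be > 0")
        if not -90 <= self.lat <= 90:
            raise ValueError(f"latitude {self.lat} out of range")
        if not -180 < self.lon <= 180:
            raise ValueError(f"longitude {self.lon} out of range")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month {self.month} out of range")


@dataclass(frozen=True)
class RectangleID:
    """An ICES statistical rectangle as (latitude band, longitude band)
    indices with the alphanumeric code (e.g. ``"31F4"``)."""

    lat_band: int
    lon_band: int
    code: str = ""


def assign_rectangle(lat: float, lon: float) -> RectangleID:
    """Map a decimal-degree coordinate (west negative) to its ICES rectangle.

    Bands are half-open ``[low, high)``, so boundary coordinates belong to
    the higher band.  Raises ``ValueError`` south of 36 deg N or outside the
    lettered longitude range (44 deg W to 68.5 deg E).
    """
    if lat < ICES_LAT_ORIGIN:
        raise ValueError(f"latitude {lat} is south of the ICES domain (36 N)")
    lat_band = math.floor((lat - ICES_LAT_ORIGIN) / 0.5)
    lon_band = math.floor(lon - ICES_LON_ORIGIN)
    if not 0 <= lon_band < _MAX_LON_BAND:
        raise ValueError(f"longitude {lon} outside the ICES rectangle grid")
    return RectangleID(lat_band, lon_band, _code_for_bands(lat_band, lon_band))


def _code_for_bands(lat_band: int, lon_band: int) -> str:
    row = f"{lat_band + 1:02d}"
    if lon_band < 4:
        return f"{row}A{lon_band}"
    idx = lon_band - 4
    return f"{row}{_WIDE_LETTERS[idx // 10]}{idx % 10}"


def rectangle_from_code(code: str) -> RectangleID:
    """Parse an ICES rectangle code such as ``"31F4"`` back to band indices."""
    code = code.strip().upper()
    if len(code) != 4 or not code[:2].isdigit() or not code[3].isdigit():
        raise ValueError(f"malformed ICES rectangle code {code!r}")
    lat_band = int(code[:2]) - 1
    letter, digit = code[2], int(code[3])
    if letter == "A":
        if digit > 3:
            raise ValueError(f"code {code!r}: column A has only digits 0-3")
        lon_band = digit
    else:
        if letter not in _WIDE_LETTERS:
            raise ValueError(f"code {code!r}: unknown column letter {letter!r}")
        lon_band = 4 + 10 * _WIDE_LETTERS.index(letter) + digit
    if lat_band < 0:
        raise ValueError(f"code {code!r}: row must be >= 01")
    return RectangleID(lat_band, lon_band, code)


def rectangle_center(rect: RectangleID) -> tuple[float, float]:
    """(lat, lon) of the rectangle's centre."""
    lat = ICES_LAT_ORIGIN + 0.5 * rect.lat_band + 0.25
    lon = ICES_LON_ORIGIN + rect.lon_band + 0.5
    return lat, lon


def season_from_month(month: int) -> str:
    """Meteorological season: Dec-Feb winter, Mar-May spring, Jun-Aug summer,
    Sep-Nov autumn."""
    if month in (12, 1, 2):
        return "winter"
    if month in (3, 4, 5):
        return "spring"
    if month in (6, 7, 8):
        return "summer"
    if month in (9, 10, 11):
        return "autumn"
    raise ValueError(f"month {month} out of range")


def previous_month(year: int, month: int) -> tuple[int, int]:
    """Calendar month preceding (year, month); January wraps to December."""
    return (year - 1, 12) if month == 1 else (year, month - 1)


class EnvLayer:
    """Gridded monthly mean SST.

    Values sit on a regular lat/lon grid; a point belongs to the cell whose
    lower-left corner is obtained by flooring to the grid (no interpolation).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        lat_res: float | None = None,
        lon_res: float | None = None,
    ) -> None:
        required = {"year", "month", "lat", "lon", "sst_c"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"SST table missing column(s): {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self.lat_res = lat_res if lat_res is not None else _infer_res(table["lat"])
        self.lon_res = lon_res if lon_res is not None else _infer_res(table["lon"])
        if not (self.lat_res > 0 and self.lon_res > 0):
            raise ValueError("grid resolution must be > 0")
        self.lat_origin = float(table["lat"].min())
        self.lon_origin = float(table["lon"].min())
        keys = zip(
            table["year"].astype(int),
            table["month"].astype(int),
            self._lat_idx(table["lat"].to_numpy()),
            self._lon_idx(table["lon"].to_numpy()),
        )
        self._cells: dict[tuple[int, int, int, int], float] = {}
        for key, sst in zip(keys, table["sst_c"].astype(float)):
            if key in self._cells:
                raise ValueError(f"duplicate SST cell {key}")
            self._cells[key] = sst

    def _lat_idx(self, lat: np.ndarray | float) -> np.ndarray:
        return np.floor((np.asarray(lat) - self.lat_origin) / self.lat_res + 1e-9).astype(int)

    def _lon_idx(self, lon: np.ndarray | float) -> np.ndarray:
        return np.floor((np.asarray(lon) - self.lon_origin) / self.lon_res + 1e-9).astype(int)

    def lookup(self, year: int, month: int, lat: float, lon: float) -> float | None:
        """Monthly mean SST of the cell containing (lat, lon), or None."""
        key = (int(year), int(month), int(self._lat_idx(lat)), int(self._lon_idx(lon)))
        return self._cells.get(key)

    @classmethod
    def read_csv(cls, path, **kwargs) -> "EnvLayer":
        return cls(pd.read_csv(path), **kwargs)


def _infer_res(coords: pd.Series) -> float:
    vals = np.unique(np.asarray(coords, dtype=float))
    if len(vals) < 2:
        return 1.0
    diffs = np.diff(vals)
    return float(diffs[diffs > 1e-9].min())


class EffortTable:
    """Annual commercial fishing effort (hours) per ICES rectangle."""

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"year", "ices_rectangle", "effort_hours"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"effort table missing column(s): {sorted(missing)}")
        if (table["effort_hours"] < 0).any():
            raise ValueError("effort must be >= 0")
        self.table = table.reset_index(drop=True)
        self._by_key: dict[tuple[int, str], float] = {}
        for year, rect, hours in zip(
            table["year"].astype(int), table["ices_rectangle"], table["effort_hours"]
        ):
            key = (year, str(rect))
            if key in self._by_key:
                raise ValueError(f"duplicate effort record for {key}")
            self._by_key[key] = float(hours)

    def lookup(self, year: int, rectangle_code: str) -> float | None:
        return self._by_key.get((int(year), rectangle_code))

    @classmethod
    def read_csv(cls, path) -> "EffortTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# readers


def read_prey_frame(path) -> pd.DataFrame:
    """Read a stomach-content CSV (one row per prey item) into a validated
    DataFrame.  Rows violating invariants (non-positive masses, zero counts,
    out-of-range coordinates or months) are dropped with a logged reason;
    a missing mandatory column raises ``ValueError`` naming it.
    """
    df = pd.read_csv(path)
    missing = [c for c in STOMACH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"stomach table missing column(s): {missing}")
    return validate_prey_frame(df)


def validate_prey_frame(df: pd.DataFrame) -> pd.DataFrame:
    checks = [
        (df["predator_mass_g"] <= 0, "non-positive predator mass"),
        (df["prey_indiv_mass_g"] <= 0, "non-positive prey mass"),
        (df["prey_count"] < 1, "prey count < 1"),
        (~df["lat"].between(-90, 90), "latitude out of range"),
        (~(df["lon"].gt(-180) & df["lon"].le(180)), "longitude out of range"),
        (~df["month"].between(1, 12), "month out of range"),
    ]
    bad = pd.Series(False, index=df.index)
    for mask, reason in checks:
        mask = mask.fillna(True) if mask.dtype == object else mask
        n_new = int((mask & ~bad).sum())
        if n_new:
            logger.warning("rejected %d prey row(s): %s", n_new, reason)
        bad |= mask
    return df.loc[~bad].reset_index(drop=True)


def read_stomach_table(path) -> list[StomachRecord]:
    """Read a stomach-content CSV into ``StomachRecord`` objects, grouping
    prey rows by ``stomach_id``."""
    df = read_prey_frame(path)
    records: list[StomachRecord] = []
    for sid, grp in df.groupby("stomach_id", sort=False):
        first = grp.iloc[0]
        prey = [
            PreyItem(
                taxon=str(r.prey_taxon),
                family=str(r.prey_family),
                count=int(r.prey_count),
                indiv_mass=float(r.prey_indiv_mass_g),
            )
            for r in grp.itertuples()
        ]
        records.append(
            StomachRecord(
                stomach_id=str(sid),
                predator_species=str(first["predator_species"]),
                predator_mass=float(first["predator_mass_g"]),
                lat=float(first["lat"]),
                lon=float(first["lon"]),
                year=int(first["year"]),
                month=int(first["month"]),
                prey=prey,
                haul_id=str(first["haul_id"]),
            )
        )
    return records


def stomach_frame(prey_df: pd.DataFrame) -> pd.DataFrame:
    """Collapse a prey-row frame to one row per stomach (stomach-level
    attributes only; prey aggregation lives in ``ppmr_core``)."""
    keep = [
        c
        for c in ["haul_id", "predator_species", "predator_mass_g", "lat", "lon", "year", "month"]
        + OPTIONAL_COVARIATE_COLUMNS
        if c in prey_df.columns
    ]
    return prey_df.groupby("stomach_id", sort=False)[keep].first().reset_index()


# ---------------------------------------------------------------------------
# matching


def match_temperature(record: StomachRecord, layer: EnvLayer) -> float | None:
    """SST for the month preceding the record's sampling month, from the grid
    cell containing the record's position; None if the layer has no covering
    cell (the record is then flagged unmatched downstream)."""
    y, m = previous_month(record.year, record.month)
    return layer.lookup(y, m, record.lat, record.lon)


def match_effort(record: StomachRecord, table: EffortTable) -> float | None:
    """Annual fishing hours for (record year, record's ICES rectangle);
    None when the table has no such record — absence is a valid outcome."""
    rect = assign_rectangle(record.lat, record.lon)
    return table.lookup(record.year, rect.code)


def build_matched_table(
    prey_df: pd.DataFrame,
    sst: EnvLayer,
    effort: EffortTable | None = None,
) -> pd.DataFrame:
    """Vectorised join used by the pipeline: adds ``ices_rectangle``,
    ``season``, ``sst_c`` (previous-month lag) and ``effort_hours`` columns
    to a prey-row frame.

    Rows with no covering SST cell get NaN ``sst_c`` and are excluded from
    analysis tables downstream; rows with no effort record stay in the
    temperature-only dataset with NaN ``effort_hours``.
    """
    df = prey_df.copy()
    df["ices_rectangle"] = [
        assign_rectangle(la, lo).code for la, lo in zip(df["lat"], df["lon"])
    ]
    df["season"] = df["month"].map(season_from_month)

    prev = [previous_month(y, m) for y, m in zip(df["year"].astype(int), df["month"].astype(int))]
    sst_keys = pd.DataFrame(
        {
            "year": [p[0] for p in prev],
            "month": [p[1] for p in prev],
            "ilat": sst._lat_idx(df["lat"].to_numpy()),
            "ilon": sst._lon_idx(df["lon"].to_numpy()),
        }
    )
    grid = sst.table.assign(
        ilat=sst._lat_idx(sst.table["lat"].to_numpy()),
        ilon=sst._lon_idx(sst.table["lon"].to_numpy()),
    )[["year", "month", "ilat", "ilon", "sst_c"]]
    merged = sst_keys.merge(grid, on=["year", "month", "ilat", "ilon"], how="left")
    df["sst_c"] = merged["sst_c"].to_numpy()
    n_unmatched = int(df["sst_c"].isna().sum())
    if n_unmatched:
        logger.warning("%d prey row(s) had no covering SST cell/month", n_unmatched)

    if effort is not None:
        eff = effort.table.rename(columns={"year": "year", "ices_rectangle": "ices_rectangle"})
        df = df.merge(
            eff[["year", "ices_rectangle", "effort_hours"]],
            on=["year", "ices_rectangle"],
            how="left",
        )
    else:
        df["effort_hours"] = np.nan
    return df
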