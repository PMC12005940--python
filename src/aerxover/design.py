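"""Time-stratified case-crossover design construction.

Each death contributes one stratum: its case day plus referent ("control")
days taken every third day before or after the case day within the same
calendar month and year — equivalently, the case day's day-of-month residue
class mod 3. A 30-day month therefore yields exactly nine referents per case
(roughly 1:9 matching) averaged over case days.

Exposure for every stratum day is the lag 0-1 moving average (mean of the
same-day and previous-day values); daily temperature is approximated as the
mean of the daily minimum and maximum before lagging. The lag-1 day of a
referent near the month start may fall in the previous month: the month
constraint applies to referent days themselves, not to their exposure
windows. Warm season is May-October, cool is November-April; the season of a
stratum — which selects the seasonal AER — is that of its case day, and no
stratum can straddle seasons because strata live within one month.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

WARM_MONTHS = frozenset({5, 6, 7, 8, 9, 10})

#: spacing of referent days around the case day, days
REFERENT_SPACING = 3


def season_of(when) -> str:
    """'warm' for May 1 - Oct 31, 'cool' for Nov 1 - Apr 30."""
    month = when.month if hasattr(when, "month") else pd.Timestamp(when).month
    return "warm" if month in WARM_MONTHS else "cool"


def referent_days(case_date) -> list[_date]:
    """Referent dates for a case day: every 3rd day within the same month.

    Returns the ascending dates {case ± 3k, k >= 1} intersected with the case
    date's calendar month, excluding the case date itself.
    """
    ts = pd.Timestamp(case_date)
    d, length = ts.day, ts.days_in_month
    first = (d - 1) % REFERENT_SPACING + 1
    days = range(first, length + 1, REFERENT_SPACING)
    return [ts.replace(day=k).date() for k in days if k != d]


def referent_count(day_of_month: int, month_length: int) -> int:
    """Closed-form referent count: floor((d-1)/3) + floor((L-d)/3)."""
    return (day_of_month - 1) // REFERENT_SPACING + \
        (month_length - day_of_month) // REFERENT_SPACING


def lag01_mean(series: pd.DataFrame, when, column: str = "pm25") -> float:
    """Lag 0-1 mean of one exposure column at ``when`` for a single cell.

    Temperature asks for the daily (tmin+tmax)/2 first; pass column='temp'.
    Raises ``KeyError`` when the day or its predecessor is absent.
    """
    ts = pd.Timestamp(when)
    s = series.set_index(pd.DatetimeIndex(series["date"]))
    if column == "temp":
        vals = (s["tmin"] + s["tmax"]) / 2.0
    else:
        vals = s[column]
    try:
        return float((vals.loc[ts] + vals.loc[ts - pd.Timedelta(days=1)]) / 2.0)
    except KeyError as err:
        raise KeyError(f"exposure missing at {when} or the previous day") from err


def lag01_table(exposures: pd.DataFrame) -> pd.DataFrame:
    """Per-(cell, date) lag 0-1 means of PM2.5, daily-mean temperature and RH.

    Rows whose lag-1 day is absent carry NaN; strata touching them are
    dropped downstream with a count.
    """
    df = exposures.sort_values(["cell_id", "date"]).copy()
    df["date"] = pd.to_datetime(df["date"])
    df["temp"] = (df["tmin"] + df["tmax"]) / 2.0
    g = df.groupby("cell_id", sort=False)
    out = df[["cell_id", "date"]].copy()
    for col, name in [("pm25", "pm_lag01"), ("temp", "temp_lag01"),
                      ("rh", "rh_lag01")]:
        prev = g[col].shift(1)
        # shift is only the previous calendar day when dates are contiguous
        contiguous = g["date"].diff() == pd.Timedelta(days=1)
        out[name] = np.where(contiguous, (df[col] + prev) / 2.0, np.nan)
    out["temp_day"] = df["temp"].to_numpy()
    return out


@dataclass
class DesignFilters:
    """Subsetting and sensitivity filters applied at design construction."""
    cause: str = "all"                  # all | cvd | respiratory
    season: str | None = None           # restrict to warm or cool strata
    max_case_temp: float | None = None  # keep strata with case-day mean T < this (°C)
    exclude_hospital: bool = False      # drop in-hospital deaths


@dataclass
class StrataBuild:
    """Long-format design rows plus construction accounting."""
    rows: pd.DataFrame
    n_strata: int
    dropped: dict[str, int] = field(default_factory=dict)


def build_strata(linked: pd.DataFrame, exposures: pd.DataFrame,
                 aer: pd.DataFrame, cells: pd.DataFrame | None = None,
                 filters: DesignFilters | None = None) -> StrataBuild:
    """Build all case-crossover strata as one long-format table.

    Parameters
    ----------
    linked : retained deaths with person_id, parcel_id, death_date, cause,
        in_hospital and either a cell_id column or geocodes (geo_x, geo_y)
        to be matched to the nearest exposure cell via ``cells``.
    exposures : long exposure table (cell_id, date, pm25, tmin, tmax, rh).
    aer : seasonal AER table (parcel_id, season, aer).
    cells : optional cell centroid table (cell_id, x, y).

    Returns a :class:`StrataBuild` whose ``rows`` hold one row per stratum
    day with columns person_id, parcel_id, date, case, pm10u, aer, temp, rh,
    dow, season, cause.
    """
    filters = filters or DesignFilters()
    deaths = linked.copy()
    deaths["death_date"] = pd.to_datetime(deaths["death_date"])

    if filters.cause != "all":
        deaths = deaths[deaths["cause"] == filters.cause]
    if filters.exclude_hospital and "in_hospital" in deaths.columns:
        deaths = deaths[~deaths["in_hospital"].astype(bool)]

    if "cell_id" not in deaths.columns:
        if cells is None:
            raise ValueError("deaths lack cell_id and no cell table given")
        from scipy.spatial import cKDTree
        tree = cKDTree(cells[["x", "y"]].to_numpy(float))
        _, idx = tree.query(deaths[["geo_x", "geo_y"]].to_numpy(float), k=1)
        deaths["cell_id"] = cells["cell_id"].to_numpy()[idx]

    dropped: dict[str, int] = {}
    n0 = len(deaths)

    if filters.season is not None:
        deaths = deaths[deaths["death_date"].map(season_of) == filters.season]
        dropped["season_filter"] = n0 - len(deaths)

    # expand each death into its mod-3 day-of-month residue class
    d = deaths["death_date"].dt.day.to_numpy()
    length = deaths["death_date"].dt.days_in_month.to_numpy()
    first = (d - 1) % REFERENT_SPACING + 1
    n_days = (length - first) // REFERENT_SPACING + 1

    rep = np.repeat(np.arange(len(deaths)), n_days)
    offsets = np.concatenate([np.arange(k) for k in n_days]) if len(deaths) else \
        np.array([], int)
    day = first[rep] + REFERENT_SPACING * offsets

    rows = pd.DataFrame({
        "person_id": deaths["person_id"].to_numpy()[rep],
        "parcel_id": deaths["parcel_id"].to_numpy()[rep],
        "cell_id": deaths["cell_id"].to_numpy()[rep],
        "cause": deaths["cause"].to_numpy()[rep] if "cause" in deaths else "all",
    })
    month_start = deaths["death_date"].to_numpy("datetime64[M]")[rep]
    rows["date"] = pd.to_datetime(month_start) + pd.to_timedelta(day - 1, "D")
    rows["case"] = (day == d[rep]).astype(int)
    warm = pd.DatetimeIndex(deaths["death_date"]).month.isin(list(WARM_MONTHS))
    rows["season"] = np.where(warm, "warm", "cool")[rep]

    # exposures at lag 0-1
    lag = lag01_table(exposures)
    rows = rows.merge(lag, on=["cell_id", "date"], how="left")

    # drop strata with any incomplete exposure row
    incomplete = rows["pm_lag01"].isna() | rows["temp_lag01"].isna() | \
        rows["rh_lag01"].isna()
    bad = rows.loc[incomplete, "person_id"].unique()
    dropped["incomplete_exposure"] = len(bad)
    if len(bad):
        rows = rows[~rows["person_id"].isin(bad)]

    # sensitivity filter: case-day daily-mean ambient temperature < threshold
    if filters.max_case_temp is not None:
        hot = rows.loc[(rows["case"] == 1) &
                       (rows["temp_day"] >= filters.max_case_temp),
                       "person_id"].unique()
        dropped["hot_case_day"] = len(hot)
        if len(hot):
            rows = rows[~rows["person_id"].isin(hot)]

    # seasonal AER of the case day's season
    rows = rows.merge(aer, on=["parcel_id", "season"], how="left")
    no_aer = rows.loc[rows["aer"].isna(), "person_id"].unique()
    dropped["missing_aer"] = len(no_aer)
    if len(no_aer):
        rows = rows[~rows["person_id"].isin(no_aer)]

    rows = rows.rename(columns={"pm_lag01": "pm10u", "temp_lag01": "temp",
                                "rh_lag01": "rh"})
    rows["pm10u"] = rows["pm10u"] / 10.0          # per 10 µg/m³
    rows["dow"] = pd.DatetimeIndex(rows["date"]).dayofweek  # Monday=0 ... Sunday=6
    rows = rows.drop(columns=["temp_day"]).reset_index(drop=True)

    # every stratum has exactly one case day within the case month
    n_cases = rows.groupby("person_id")["case"].sum()
    assert (n_cases == 1).all(), "stratum without exactly one case day"

    return StrataBuild(rows=rows, n_strata=rows["person_id"].nunique(),
                       dropped=dropped)
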