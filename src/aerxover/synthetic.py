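"""Synthetic parcels, exposure series and death records with known truth.

The generator emulates the three inputs of the analysis — a cadastral parcel
table, daily gridded exposure series (PM2.5, temperature, relative humidity)
and geocoded death records — with the statistical structure the case-crossover
design assumes, so the whole pipeline is testable end to end and the fitted
conditional-logistic coefficients can be compared against the planted truth.

Case-day timing is simulated by *exact within-month conditional sampling*:
a (parcel, month) stratum is drawn first, then the case day within that month
with probability proportional to exp(eta_d), where eta_d is the same linear
predictor the analysis model fits (lag 0-1 PM2.5 per 10 µg/m³, its product
with the parcel's seasonal AER, temperature and humidity per 10 units, and
day-of-week offsets with Sunday fixed at zero). Because the every-third-day
referent sets partition each month into day-of-month residue classes, the
conditional-logistic estimand equals the data-generating parameters by
construction and recovery tests are sharp.

All randomness flows from one master seed through per-entity substreams
derived by stable hashing, so outputs are reproducible and independent of
iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import lag01_table, season_of

__all__ = [
    "GeometryConfig", "ParcelMixConfig", "ClimateFieldConfig", "CohortConfig",
    "TruthParams", "generate_parcels", "generate_exposures",
    "simulate_case_days", "case_day_probabilities",
]


def substream(seed: int, *keys) -> np.random.Generator:
    """Independent generator for (seed, entity) derived by stable hashing."""
    entropy = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryConfig:
    """Projected study region: a square box, metres."""
    extent: float = 50_000.0
    parcel_spacing_jitter: float = 1.0   # unused placeholder for future grids


@dataclass(frozen=True)
class ParcelMixConfig:
    """Composition of the parcel table.

    ``type_probs`` covers MAPC-style residential types 1-5 (single family,
    duplex/triplex, small apartments, large apartments, multiuse residential),
    livable nonresidential parcels, and nonresidential parcels in excluded
    land-use categories. ``zero_area_frac`` plants parcels with a recorded
    building area of zero to exercise the exclusion filters.
    """
    type_probs: dict = field(default_factory=lambda: {
        1: 0.42, 2: 0.10, 3: 0.08, 4: 0.06, 5: 0.04,
        "NONRES": 0.22, "EXCLUDED": 0.08,
    })
    year_range: tuple[int, int] = (1850, 2015)
    area_log_mean: float = float(np.log(180.0))   # m², lognormal body
    area_log_sd: float = 0.5
    zero_area_frac: float = 0.05
    affordable_frac_nonres: float = 0.03


@dataclass(frozen=True)
class ClimateFieldConfig:
    """Daily exposure process per grid cell.

    PM2.5 is lognormal around a seasonal cycle peaking in summer with AR(1)
    day-to-day dependence on the log scale; temperature follows a sinusoidal
    annual cycle with autocorrelated noise and a diurnal min/max spread;
    relative humidity is autocorrelated noise clipped to [0, 100].
    """
    pm_log_mean: float = float(np.log(8.0))   # µg/m³ geometric mean
    pm_log_amp: float = 0.25                  # summer-peaking log amplitude
    pm_ar1: float = 0.6                       # lag-1 autocorrelation, log scale
    pm_log_sd: float = 0.5                    # marginal sd of the AR(1) part
    temp_mean: float = 9.4                    # °C annual mean
    temp_amp: float = 12.5                    # °C annual amplitude
    temp_noise_sd: float = 3.0
    temp_ar1: float = 0.6
    diurnal_spread: float = 8.0               # tmax - tmin, °C
    diurnal_spread_sd: float = 1.0
    rh_mean: float = 64.5                     # %
    rh_amp: float = 4.0
    rh_noise_sd: float = 8.0
    rh_ar1: float = 0.5
    peak_doy: int = 196                       # mid-July


@dataclass(frozen=True)
class TruthParams:
    """Planted log-odds effects, on the analysis model's reporting scales.

    ``theta1``: log-odds per 10 µg/m³ PM2.5 at AER = 0 (default 0.02, an OR
    of 1.02 per 10 µg/m³). ``theta3``: additional log-odds per 10 µg/m³ per
    unit (hour^-1) AER (default 0.14, an interaction OR of 1.15).
    ``dow_effects`` are Monday..Sunday offsets with Sunday fixed at 0 for
    identification.
    """
    theta1: float = 0.02
    theta3: float = 0.14
    gamma_temp: float = 0.005   # per 10 °C
    gamma_rh: float = 0.005     # per 10 % RH
    dow_effects: tuple = (0.01, 0.02, 0.02, 0.01, 0.0, -0.02, 0.0)

    def __post_init__(self):
        vals = [self.theta1, self.theta3, self.gamma_temp, self.gamma_rh,
                *self.dow_effects]
        if not np.all(np.isfinite(vals)):
            raise ValueError("truth parameters must be finite")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")
        if self.dow_effects[6] != 0.0:
            raise ValueError("Sunday offset must be 0 for identification")


@dataclass(frozen=True)
class CohortConfig:
    """Death-record nuisance structure."""
    jitter_probs: tuple = (0.90, 0.08, 0.02)          # <1 m, 1-10 m, >10 m
    jitter_radii: tuple = ((0.0, 1.0), (1.0, 10.0), (10.0, 25.0))
    in_hospital_rate: float = 0.40
    cause_probs: dict = field(default_factory=lambda: {
        "cvd": 0.334, "respiratory": 0.111})          # remainder: other causes
    age_mean: float = 78.1
    age_sd: float = 13.1
    age_range: tuple = (40.0, 110.0)


# ---------------------------------------------------------------------------
# parcels
# ---------------------------------------------------------------------------

_EXCL_CODES = ("agriculture_recreation", "educational",
               "industrial_warehouse_utilities")


def generate_parcels(n: int, geometry: GeometryConfig | None = None,
                     mix: ParcelMixConfig | None = None, seed: int = 0
                     ) -> pd.DataFrame:
    """Parcel table: id, coordinates, type, vintage, size, stories, units.

    Residential types 1-5 and nonresidential parcels are mixed at the
    configured proportions; a configurable fraction records zero building
    area and another carries an excluded land-use category, so downstream
    exclusion filters have something to do.
    """
    if n < 1:
        raise ValueError("need at least one parcel")
    geometry = geometry or GeometryConfig()
    mix = mix or ParcelMixConfig()
    rng = substream(seed, "parcels")

    cats = list(mix.type_probs)
    probs = np.array([mix.type_probs[c] for c in cats], float)
    probs = probs / probs.sum()
    cat = rng.choice(len(cats), size=n, p=probs)
    cat = np.array(cats, object)[cat]

    excluded = cat == "EXCLUDED"
    nonres = (cat == "NONRES") | excluded
    retype = np.where(nonres, "NONRES", cat)
    excl_cat = np.where(excluded, rng.choice(_EXCL_CODES, size=n), None)

    year = rng.integers(mix.year_range[0], mix.year_range[1] + 1, size=n)
    area = rng.lognormal(mix.area_log_mean, mix.area_log_sd, size=n)
    # apartments and nonresidential buildings are bigger
    big = np.isin(cat, [3, 4, 5]) | nonres
    area = np.where(big, area * rng.uniform(3.0, 10.0, size=n), area)
    area = np.where(rng.random(n) < mix.zero_area_frac, 0.0, area)

    stories = np.where(
        np.isin(cat, [3, 4]), rng.integers(2, 7, size=n),
        rng.choice([1, 2, 3], size=n, p=[0.45, 0.40, 0.15]))

    units = np.select(
        [cat == 1, cat == 2, cat == 3, cat == 4, cat == 5],
        [np.ones(n), rng.integers(2, 4, n), rng.integers(4, 12, n),
         rng.integers(12, 61, n), rng.integers(2, 9, n)],
        default=rng.choice([0, 0, 0, 1, 4, 12], size=n),
    ).astype(int)

    afford = nonres & (rng.random(n) < mix.affordable_frac_nonres)

    return pd.DataFrame({
        "parcel_id": np.arange(n),
        "x": rng.uniform(0, geometry.extent, n),
        "y": rng.uniform(0, geometry.extent, n),
        "real_estate_type": [int(c) if not isinstance(c, str) else "NONRES"
                             for c in cat],
        "year_built": year,
        "building_area": area,
        "stories": stories,
        "housing_units": units,
        "affordable_housing": afford,
        "excl_category": excl_cat,
    })


# ---------------------------------------------------------------------------
# exposures
# ---------------------------------------------------------------------------

def _ar1(rng, n, phi, marginal_sd):
    """Stationary AR(1) path with the given marginal standard deviation."""
    if marginal_sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = marginal_sd * np.sqrt(max(1.0 - phi * phi, 1e-12))
    e = rng.normal(0.0, innov_sd, n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, marginal_sd)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def generate_exposures(cells: int, span: tuple, geometry: GeometryConfig | None = None,
                       climate: ClimateFieldConfig | None = None, seed: int = 0
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily exposure series per grid cell, plus the cell centroid table.

    ``span`` is an inclusive (start, end) date pair. Returns
    ``(exposures, cells)`` where exposures is long format
    (cell_id, date, pm25, tmin, tmax, rh) with contiguous dates per cell, and
    cells holds (cell_id, x, y) centroids on a regular grid over the region.
    """
    geometry = geometry or GeometryConfig()
    climate = climate or ClimateFieldConfig()
    start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    if end < start:
        raise ValueError("empty date span")
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy(float)
    phase = 2 * np.pi * (doy - climate.peak_doy) / 365.25

    side = int(np.ceil(np.sqrt(cells)))
    step = geometry.extent / side
    cx, cy = np.meshgrid(np.arange(side), np.arange(side))
    centroids = pd.DataFrame({
        "cell_id": np.arange(side * side),
        "x": (cx.ravel() + 0.5) * step,
        "y": (cy.ravel() + 0.5) * step,
    }).iloc[:cells].reset_index(drop=True)

    frames = []
    for cid in centroids["cell_id"]:
        rng = substream(seed, "exposure", cid)
        logpm = (climate.pm_log_mean + climate.pm_log_amp * np.cos(phase)
                 + _ar1(rng, n, climate.pm_ar1, climate.pm_log_sd))
        tmean = (climate.temp_mean + climate.temp_amp * np.cos(phase)
                 + _ar1(rng, n, climate.temp_ar1, climate.temp_noise_sd))
        spread = np.maximum(
            climate.diurnal_spread
            + rng.normal(0.0, climate.diurnal_spread_sd, n), 0.0)
        rh = np.clip(
            climate.rh_mean - climate.rh_amp * np.cos(phase)
            + _ar1(rng, n, climate.rh_ar1, climate.rh_noise_sd), 0.0, 100.0)
        frames.append(pd.DataFrame({
            "cell_id": cid, "date": dates, "pm25": np.exp(logpm),
            "tmin": tmean - spread / 2.0, "tmax": tmean + spread / 2.0,
            "rh": rh,
        }))
    return pd.concat(frames, ignore_index=True), centroids


# ---------------------------------------------------------------------------
# deaths
# ---------------------------------------------------------------------------

def case_day_probabilities(pm10: np.ndarray, temp: np.ndarray, rh: np.ndarray,
                           dow: np.ndarray, aer: float, truth: TruthParams
                           ) -> np.ndarray:
    """Normalised within-month case-day probabilities for one stratum.

    Inputs are per-day lag 0-1 means over the calendar month (PM2.5 already
    per 10 µg/m³) plus the parcel's seasonal AER. The softmax of the linear
    predictor defines the sampling distribution; the probabilities sum to 1
    over the eligible days by construction.
    """
    dow_eff = np.asarray(truth.dow_effects, float)[np.asarray(dow, int)]
    eta = (truth.theta1 * pm10 + truth.theta3 * pm10 * aer
           + truth.gamma_temp * np.asarray(temp, float) / 10.0
           + truth.gamma_rh * np.asarray(rh, float) / 10.0 + dow_eff)
    eta = eta - eta.max()
    w = np.exp(eta)
    return w / w.sum()


def _candidate_months(dates: pd.DatetimeIndex) -> list[pd.Timestamp]:
    """Month starts whose whole month plus the lag-1 lead-in lie in ``dates``."""
    have = set(pd.DatetimeIndex(dates).normalize())
    months = pd.date_range(min(have).replace(day=1), max(have), freq="MS")
    out = []
    for m in months:
        m_end = m + pd.offsets.MonthEnd(0)
        needed = pd.date_range(m - pd.Timedelta(days=1), m_end, freq="D")
        if all(d in have for d in needed):
            out.append(m)
    return out


def simulate_case_days(parcels: pd.DataFrame, aer: pd.DataFrame,
                       exposures: pd.DataFrame, cells: pd.DataFrame,
                       truth: TruthParams | None = None, n_deaths: int = 1000,
                       seed: int = 0, config: CohortConfig | None = None
                       ) -> pd.DataFrame:
    """Simulate death records with within-month case-day timing.

    Every death draws a (parcel, month) stratum uniformly — parcels from the
    AER-eligible set (AER available for both seasons, building area > 0) and
    months from those fully covered by the exposure span including the lag-1
    lead-in day — then its case day from the softmax of the planted linear
    predictor. Geocodes sit at the parcel centroid plus radial jitter (a
    configurable tail beyond 10 m exercises the linkage exclusions);
    in-hospital flags, cause classes and ages are nuisance structure.
    """
    truth = truth or TruthParams()
    config = config or CohortConfig()
    rng = substream(seed, "deaths")

    aer_wide = aer.pivot(index="parcel_id", columns="season", values="aer")
    eligible_ids = aer_wide.dropna().index
    pool = parcels.set_index("parcel_id").loc[eligible_ids]
    pool = pool[pool["building_area"] > 0]
    if len(pool) == 0:
        raise ValueError("no AER-eligible parcels to draw deaths from")

    lag = lag01_table(exposures)
    lag = lag.dropna(subset=["pm_lag01", "temp_lag01", "rh_lag01"])
    months = _candidate_months(pd.DatetimeIndex(pd.to_datetime(
        exposures["date"]).unique()))
    if not months:
        raise ValueError("exposure span does not cover any full month plus "
                         "its lag-1 lead-in day")

    # map each eligible parcel to its nearest exposure cell
    from scipy.spatial import cKDTree
    tree = cKDTree(cells[["x", "y"]].to_numpy(float))
    _, ci = tree.query(pool[["x", "y"]].to_numpy(float), k=1)
    pool = pool.assign(cell_id=cells["cell_id"].to_numpy()[ci])

    pidx = rng.integers(0, len(pool), n_deaths)
    midx = rng.integers(0, len(months), n_deaths)
    u = rng.random(n_deaths)

    lag = lag.set_index(["cell_id", "date"]).sort_index()
    death_date = np.empty(n_deaths, "datetime64[ns]")
    order = pd.DataFrame({"pidx": pidx, "midx": midx})
    pool_cell = pool["cell_id"].to_numpy()

    aer_cols = aer_wide.loc[pool.index]
    aer_warm = aer_cols["warm"].to_numpy(float)
    aer_cool = aer_cols["cool"].to_numpy(float)

    for (cell, mi), grp in order.groupby([pool_cell[pidx], "midx"]):
        m = months[mi]
        mdays = pd.date_range(m, m + pd.offsets.MonthEnd(0), freq="D")
        try:
            sub = lag.loc[(cell,)].loc[mdays]
        except KeyError as err:
            raise ValueError(f"missing exposure coverage for cell {cell} "
                             f"in {m:%Y-%m}") from err
        if sub[["pm_lag01", "temp_lag01", "rh_lag01"]].isna().any().any():
            raise ValueError(f"missing exposure coverage for cell {cell} "
                             f"in {m:%Y-%m}")
        pm10 = sub["pm_lag01"].to_numpy(float) / 10.0
        temp = sub["temp_lag01"].to_numpy(float)
        rh = sub["rh_lag01"].to_numpy(float)
        dow = mdays.dayofweek.to_numpy()
        season = season_of(m)
        a = (aer_warm if season == "warm" else aer_cool)[grp["pidx"].to_numpy()]

        dow_eff = np.asarray(truth.dow_effects, float)[dow]
        base = (truth.theta1 * pm10 + truth.gamma_temp * temp / 10.0
                + truth.gamma_rh * rh / 10.0 + dow_eff)
        eta = base[None, :] + truth.theta3 * np.outer(a, pm10)
        eta -= eta.max(axis=1, keepdims=True)
        w = np.exp(eta)
        cdf = np.cumsum(w, axis=1)
        cdf /= cdf[:, [-1]]
        day_ix = (cdf < u[grp.index.to_numpy()][:, None]).sum(axis=1)
        death_date[grp.index.to_numpy()] = mdays.to_numpy()[day_ix]

    # geocode jitter around the parcel centroid
    tier = rng.choice(len(config.jitter_probs), size=n_deaths,
                      p=np.asarray(config.jitter_probs) / np.sum(config.jitter_probs))
    radii = np.array(config.jitter_radii, float)
    r = rng.uniform(radii[tier, 0], radii[tier, 1])
    ang = rng.uniform(0, 2 * np.pi, n_deaths)

    causes = list(config.cause_probs)
    cprob = np.array([config.cause_probs[c] for c in causes], float)
    cause = np.where(
        rng.random(n_deaths) < cprob.sum(),
        np.array(causes, object)[rng.choice(len(causes), n_deaths,
                                            p=cprob / cprob.sum())],
        "other")

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n_deaths),
                  *config.age_range)

    px = pool["x"].to_numpy()[pidx]
    py = pool["y"].to_numpy()[pidx]
    return pd.DataFrame({
        "person_id": np.arange(n_deaths),
        "geo_x": px + r * np.cos(ang),
        "geo_y": py + r * np.sin(ang),
        "death_date": death_date,
        "cause": cause,
        "age": age,
        "in_hospital": rng.random(n_deaths) < config.in_hospital_rate,
        "source_parcel_id": pool.index.to_numpy()[pidx],
        "cell_id": pool_cell[pidx],
    })
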