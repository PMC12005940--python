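"""Parcel-level structural air exchange rates from building physics.

The structural air exchange rate (AER, hour^-1) of a building envelope is the
product of a *normalized leakage* (NL) — a dimensionless leakiness predicted
from building age and floor area by a log-linear regression — and an
*infiltration factor* combining the stack effect (buoyancy from the
indoor-outdoor temperature difference, growing with building height) and wind
pressure, scaled to the conditioned-volume height:

    NL  = exp(b0 + b_year * year_built + b_area * area [+ low-income offset])
    s   = sqrt( f_s(stories) * |T_in - T_out|  +  f_w * (shielding * wind)^2 )
    AER = NL * s * h_ref / (stack_stories * story_height)

Only envelope leakage is modelled: window opening and mechanical ventilation
(HVAC) are deliberately out of scope. Multifamily parcels use per-unit floor
area (building_area / housing_units) in the leakage regression and a stack
height of half the building's stories; nonresidential parcels get a
configurable leakage multiplier. All coefficients are configuration, not
constants: the regression values are data, the formula structure is the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkage import classify_housing

SEASONS = ("warm", "cool")


@dataclass(frozen=True)
class AERConfig:
    """Coefficients and physical constants of the infiltration model.

    ``fs`` is the one-story stack coefficient ((h^-1)^2 per °C); the effective
    stack coefficient grows linearly with the stack height in stories, the
    standard LBNL pattern. ``fw`` is the wind coefficient ((h^-1)^2 per
    (m/s)^2). Indoor set points default to 20 °C in both seasons.
    """
    nl_intercept: float = 11.78
    nl_coef_year: float = -0.0059   # per calendar year; newer -> tighter
    nl_coef_area: float = -0.0004   # per m²; larger homes leak less per area
    fs: float = 0.015
    fw: float = 0.0065
    indoor_temp_warm: float = 20.0
    indoor_temp_cool: float = 20.0
    story_height: float = 2.5       # m
    reference_height: float = 2.5   # m; h_ref in the AER combination rule
    low_income_adjustment: float = 0.0  # additive log-NL offset when flagged
    nonres_scaling: float = 0.5     # leakage multiplier for nonresidential
    wind_shielding: float = 1.0     # land-use shielding multiplier on wind

    def __post_init__(self):
        if self.fs < 0 or self.fw < 0:
            raise ValueError("stack and wind factors must be nonnegative")
        if self.story_height <= 0:
            raise ValueError("story_height must be positive")

    def indoor_temp(self, season: str) -> float:
        return self.indoor_temp_warm if season == "warm" else self.indoor_temp_cool


@dataclass(frozen=True)
class ClimateNormals:
    """Seasonal wind speed (m/s) and ambient temperature (°C) for a location."""
    season: str
    wind_speed: float
    ambient_temp: float
    location_id: str = "default"

    def __post_init__(self):
        if self.wind_speed < 0:
            raise ValueError("wind speed must be nonnegative")
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}")


#: Massachusetts-flavoured seasonal normals used throughout the synthetic study
DEFAULT_CLIMATE: dict[str, ClimateNormals] = {
    "warm": ClimateNormals("warm", wind_speed=3.5, ambient_temp=17.0),
    "cool": ClimateNormals("cool", wind_speed=5.0, ambient_temp=2.0),
}


def normalized_leakage(year_built, building_area, config: AERConfig,
                       low_income=False):
    """Dimensionless normalized leakage from the log-linear regression.

    Accepts scalars or arrays. Raises on nonpositive area or missing
    year_built — zero-area parcels must be excluded upstream.
    """
    year = np.asarray(year_built, float)
    area = np.asarray(building_area, float)
    if np.any(~np.isfinite(year)):
        raise ValueError("year_built missing or non-finite")
    if np.any(~(area > 0)):
        raise ValueError("building_area must be positive (zero-area parcels "
                         "are excluded upstream)")
    lp = (config.nl_intercept + config.nl_coef_year * year
          + config.nl_coef_area * area)
    lp = lp + np.where(np.asarray(low_income, bool),
                       config.low_income_adjustment, 0.0)
    out = np.exp(lp)
    return out if out.ndim else float(out)


def infiltration_factor(climate: ClimateNormals, config: AERConfig,
                        stories=1.0):
    """Stack-plus-wind infiltration factor s >= 0 for a season.

    s = sqrt(fs * stories * |dT| + fw * (shielding * wind)^2); zero exactly
    when both the temperature difference and the wind vanish.
    """
    if climate.wind_speed < 0:
        raise ValueError("wind speed must be nonnegative")
    st = np.asarray(stories, float)
    if np.any(st < 1):
        raise ValueError("stories must be >= 1")
    dt = abs(config.indoor_temp(climate.season) - climate.ambient_temp)
    wind = config.wind_shielding * climate.wind_speed
    s = np.sqrt(config.fs * st * dt + config.fw * wind * wind)
    return s if s.ndim else float(s)


def seasonal_aer(parcels: pd.DataFrame, climate: ClimateNormals,
                 config: AERConfig | None = None) -> pd.DataFrame:
    """Structural AER (hour^-1) for every parcel in one season.

    Multifamily parcels (see :func:`aerxover.linkage.classify_housing`) use
    per-unit floor area in the leakage regression and half the building's
    stories as the representative stack height; nonresidential parcels apply
    ``nonres_scaling`` to the leakage. Returns columns
    ``parcel_id, season, aer``.
    """
    config = config or AERConfig()
    housing = classify_housing(parcels)
    multi = (housing["housing_type"] == "multifamily").to_numpy()
    res = housing["residential"].to_numpy()

    area = parcels["building_area"].to_numpy(float)
    units = parcels["housing_units"].to_numpy(float)
    per_unit = multi & (units >= 2)
    eff_area = np.where(per_unit, area / np.maximum(units, 1.0), area)

    low_inc = (parcels["affordable_housing"].to_numpy(bool)
               if "affordable_housing" in parcels else False)
    nl = normalized_leakage(parcels["year_built"].to_numpy(float), eff_area,
                            config, low_income=low_inc)
    nl = np.where(res, nl, nl * config.nonres_scaling)

    stories = parcels["stories"].to_numpy(float)
    stack_stories = np.where(multi, np.maximum(1.0, stories / 2.0), stories)
    s = infiltration_factor(climate, config, stories=stack_stories)

    height = stack_stories * config.story_height
    aer = nl * s * config.reference_height / height
    return pd.DataFrame({
        "parcel_id": parcels["parcel_id"].to_numpy(),
        "season": climate.season,
        "aer": aer,
    })


def seasonal_aer_table(parcels: pd.DataFrame,
                       climate: dict[str, ClimateNormals] | None = None,
                       config: AERConfig | None = None) -> pd.DataFrame:
    """AER for both seasons, long format (parcel_id, season, aer)."""
    climate = climate or DEFAULT_CLIMATE
    parts = [seasonal_aer(parcels, climate[s], config) for s in SEASONS]
    return pd.concat(parts, ignore_index=True)
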