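"""End-to-end convenience wrappers: simulate, link, design, fit in one call.

These are thin compositions of the stage modules, used by the command-line
interface, the test suite's replicated simulations, and anyone who wants the
whole analysis on synthetic data without wiring the stages by hand. The
expensive static inputs (parcels, AER, exposures) can be generated once and
reused across replicated death draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import aer as aer_mod
from . import clogit, linkage, synthetic
from .design import DesignFilters, StrataBuild, build_strata


@dataclass
class StudyInputs:
    """Static synthetic inputs shared across replicated death draws."""
    parcels: pd.DataFrame
    aer: pd.DataFrame
    exposures: pd.DataFrame
    cells: pd.DataFrame


def make_study_inputs(n_parcels: int = 2000, n_cells: int = 4,
                      span: tuple = ("2009-12-01", "2011-12-31"),
                      seed: int = 0,
                      aer_config: aer_mod.AERConfig | None = None,
                      geometry: synthetic.GeometryConfig | None = None
                      ) -> StudyInputs:
    """Parcels, their seasonal AERs, and exposure series for one study."""
    geometry = geometry or synthetic.GeometryConfig()
    parcels = synthetic.generate_parcels(n_parcels, geometry=geometry,
                                         seed=seed)
    eligible = parcels[parcels["building_area"] > 0]
    aer = aer_mod.seasonal_aer_table(eligible, config=aer_config)
    exposures, cells = synthetic.generate_exposures(
        n_cells, span, geometry=geometry, seed=seed)
    return StudyInputs(parcels=parcels, aer=aer, exposures=exposures,
                       cells=cells)


def simulate_and_design(inputs: StudyInputs,
                        truth: synthetic.TruthParams | None = None,
                        n_deaths: int = 2000, seed: int = 0,
                        filters: DesignFilters | None = None,
                        link: bool = False) -> StrataBuild:
    """Draw deaths and build the case-crossover design rows.

    With ``link=True`` deaths go through nearest-parcel matching and the
    exclusion filters (exercising the full pipeline); otherwise the known
    source parcel is used directly, which is what parameter-recovery
    simulations want since linkage noise is not part of the estimand.
    """
    deaths = synthetic.simulate_case_days(
        inputs.parcels, inputs.aer, inputs.exposures, inputs.cells,
        truth=truth, n_deaths=n_deaths, seed=seed)
    if link:
        linked = linkage.link_deaths(deaths, inputs.parcels)
        linked, _ = linkage.apply_exclusions(linked, inputs.parcels)
    else:
        linked = deaths.rename(columns={"source_parcel_id": "parcel_id"})
    return build_strata(linked, inputs.exposures, inputs.aer,
                        cells=inputs.cells, filters=filters)


INTERACTION_SPEC = clogit.ModelSpec(covariates=("pm10u", "temp10u", "rh10u"),
                                    dow=True, interaction=("pm10u", "aer"))
MAIN_SPEC = clogit.ModelSpec(covariates=("pm10u", "temp10u", "rh10u"),
                             dow=True, interaction=None)


def fit_interaction(rows: pd.DataFrame, **kwargs) -> clogit.FitResult:
    """Fit the product-term conditional-logistic model on design rows."""
    return clogit.fit(INTERACTION_SPEC, rows, **kwargs)


def fit_main(rows: pd.DataFrame, **kwargs) -> clogit.FitResult:
    """Fit the main-effects-only model on design rows."""
    return clogit.fit(MAIN_SPEC, rows, **kwargs)
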