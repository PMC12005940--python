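"""Death-to-parcel linkage, exclusion filters, and housing classification.

Each geocoded death is matched to its nearest parcel (point-to-centroid
Euclidean distance; parcels are points in this pipeline). Matches are then
filtered: deaths linked to excluded nonresidential land-use categories
(agriculture/recreation, educational, industrial/warehouse/utilities), to
parcels with zero building area, or lying more than 10 m from any parcel are
dropped, with full accounting of each category.

Because a record can fail several filters at once, the report carries two
views: *sequential* counts (a record is charged to the first filter it fails,
in the order category -> zero-area -> distance) and *overlap-aware* counts
(how many records fail each filter regardless of the others). The two views
coincide only when the filters are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

RESIDENTIAL_TYPES = frozenset({1, 2, 3, 4, 5})

#: nonresidential land-use categories whose deaths are excluded outright
EXCLUDED_CATEGORIES = frozenset({"agriculture_recreation", "educational",
                                 "industrial_warehouse_utilities"})

#: maximum geocode-to-parcel distance retained, metres
MAX_LINK_DISTANCE_M = 10.0


# ---------------------------------------------------------------------------
# nearest-parcel matching
# ---------------------------------------------------------------------------

def nearest_parcel(geocode: tuple[float, float], parcels: pd.DataFrame
                   ) -> tuple[object, float]:
    """Match one geocode to the nearest parcel centroid.

    Ties in Euclidean distance are broken deterministically by the smallest
    ``parcel_id``. Raises ``ValueError`` on an empty parcel table.
    """
    if len(parcels) == 0:
        raise ValueError("cannot match against an empty parcel set")
    dx = parcels["x"].to_numpy(float) - geocode[0]
    dy = parcels["y"].to_numpy(float) - geocode[1]
    d2 = dx * dx + dy * dy
    best = d2.min()
    cand = np.flatnonzero(d2 == best)
    ids = parcels["parcel_id"].to_numpy()
    winner = cand[np.argsort(ids[cand], kind="stable")[0]]
    return ids[winner], float(np.sqrt(best))


def link_deaths(deaths: pd.DataFrame, parcels: pd.DataFrame) -> pd.DataFrame:
    """Vectorised nearest-parcel linkage for a death table.

    Returns the death table with ``parcel_id`` and ``distance`` columns
    appended.  Uses a k-d tree for the bulk query; exact ties (rare with
    floating geocodes, common in constructed fixtures) are re-resolved by
    smallest parcel_id among equidistant candidates.
    """
    if len(parcels) == 0:
        raise ValueError("cannot match against an empty parcel set")
    pts = parcels[["x", "y"]].to_numpy(float)
    tree = cKDTree(pts)
    q = deaths[["geo_x", "geo_y"]].to_numpy(float)
    dist, idx = tree.query(q, k=1)

    # deterministic tie-break: query a couple more neighbours and pick the
    # smallest parcel_id among exact-distance ties
    k = min(4, len(parcels))
    if k > 1:
        dk, ik = tree.query(q, k=k)
        ids = parcels["parcel_id"].to_numpy()
        tied = dk == dk[:, [0]]
        cand_ids = np.where(tied, ids[ik], np.inf if np.issubdtype(
            ids.dtype, np.number) else None)
        if np.issubdtype(ids.dtype, np.number):
            pick = np.argmin(cand_ids, axis=1)
        else:
            # lexicographic min over object ids
            pick = np.array([min((j for j in range(k) if tied[i, j]),
                                 key=lambda j: ids[ik[i, j]])
                             for i in range(len(q))])
        idx = ik[np.arange(len(q)), pick]
        dist = dk[np.arange(len(q)), pick]

    out = deaths.copy()
    out["parcel_id"] = parcels["parcel_id"].to_numpy()[idx]
    out["distance"] = dist
    return out


# ---------------------------------------------------------------------------
# exclusion filters
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    """Accounting of the linkage exclusions.

    ``sequential`` charges each record to the first filter it fails, in the
    order excluded-category, zero building area, distance > 10 m, so the
    counts sum to ``total - retained``.  ``overlapping`` counts every filter a
    record fails, so the counts can exceed ``total - retained``.
    """
    total: int
    retained: int
    sequential: dict[str, int]
    overlapping: dict[str, int]
    retained_by_cause: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
        """Share of ``numerator`` in ``denominator`` as a percentage, rounded."""
        if denominator == 0:
            return 0.0
        return round(100.0 * numerator / denominator, decimals)

    @property
    def excluded(self) -> int:
        return self.total - self.retained

    def percentages(self) -> dict[str, float]:
        """Each sequential category, plus the overall exclusion, as % of total."""
        out = {k: self.percent(v, self.total) for k, v in self.sequential.items()}
        out["excluded_total"] = self.percent(self.excluded, self.total)
        return out

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "retained": self.retained,
            "excluded": self.excluded,
            "sequential": dict(self.sequential),
            "overlapping": dict(self.overlapping),
            "percentages": self.percentages(),
            "retained_by_cause": dict(self.retained_by_cause),
        }

    def to_text(self) -> str:
        pct = self.percentages()
        lines = [f"linked deaths: {self.total}"]
        for key, label in [("excluded_nonres_category", "excluded nonresidential category"),
                           ("excluded_zero_area", "zero building area"),
                           ("excluded_far", f"> {MAX_LINK_DISTANCE_M:g} m from parcel")]:
            lines.append(f"  {label}: {self.sequential.get(key, 0)} "
                         f"({pct.get(key, 0.0):.2f}%) "
                         f"[any: {self.overlapping.get(key, 0)}]")
        lines.append(f"retained: {self.retained} "
                     f"(excluded {self.excluded}, {pct['excluded_total']:.2f}%)")
        for cause, n in self.retained_by_cause.items():
            lines.append(f"  retained {cause}: {n} "
                         f"({self.percent(n, self.retained):.2f}%)")
        return "\n".join(lines)


def apply_exclusions(linked: pd.DataFrame, parcels: pd.DataFrame
                     ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the three exclusion filters and account for every record.

    Parameters
    ----------
    linked : deaths with ``parcel_id`` and ``distance`` (from :func:`link_deaths`)
    parcels : parcel table with ``excl_category`` and ``building_area``

    Returns the retained subset (with ``residential`` and ``housing_type``
    columns appended) and an :class:`ExclusionReport`.
    """
    total = len(linked)
    if total == 0:
        rep = ExclusionReport(0, 0,
                              {"excluded_nonres_category": 0,
                               "excluded_zero_area": 0, "excluded_far": 0},
                              {"excluded_nonres_category": 0,
                               "excluded_zero_area": 0, "excluded_far": 0})
        return linked.copy(), rep

    pcols = parcels.set_index("parcel_id")
    cat = pcols["excl_category"].reindex(linked["parcel_id"]).to_numpy(object)
    area = pcols["building_area"].reindex(linked["parcel_id"]).to_numpy(float)

    bad_cat = np.array([c in EXCLUDED_CATEGORIES for c in cat])
    bad_area = area <= 0
    bad_far = linked["distance"].to_numpy(float) > MAX_LINK_DISTANCE_M

    seq_cat = bad_cat
    seq_area = bad_area & ~seq_cat
    seq_far = bad_far & ~seq_cat & ~bad_area

    keep = ~(bad_cat | bad_area | bad_far)
    retained = linked.loc[keep].copy()

    housing = classify_housing(pcols.reindex(retained["parcel_id"]).reset_index())
    retained["residential"] = housing["residential"].to_numpy()
    retained["housing_type"] = housing["housing_type"].to_numpy()

    by_cause: dict[str, int] = {}
    if "cause" in retained.columns:
        by_cause["all"] = len(retained)
        for c in ("cvd", "respiratory"):
            by_cause[c] = int((retained["cause"] == c).sum())

    rep = ExclusionReport(
        total=total,
        retained=int(keep.sum()),
        sequential={"excluded_nonres_category": int(seq_cat.sum()),
                    "excluded_zero_area": int(seq_area.sum()),
                    "excluded_far": int(seq_far.sum())},
        overlapping={"excluded_nonres_category": int(bad_cat.sum()),
                     "excluded_zero_area": int(bad_area.sum()),
                     "excluded_far": int(bad_far.sum())},
        retained_by_cause=by_cause,
    )
    return retained, rep


# ---------------------------------------------------------------------------
# housing classification
# ---------------------------------------------------------------------------

def classify_housing(parcels: pd.DataFrame) -> pd.DataFrame:
    """Classify parcels as residential/nonresidential and single/multifamily.

    Rules: real-estate types 1-5 are residential; type 1 is single-family and
    types 2-5 multifamily. Nonresidential parcels that nevertheless house
    people (nursing homes, municipal buildings, ...) are single-family when
    they hold fewer than two estimated housing units, multifamily otherwise;
    any nonresidential parcel flagged as affordable housing is multifamily
    regardless of its unit count.
    """
    def _norm(t):
        # CSV round-trips render residential codes as strings
        if isinstance(t, str) and t.isdigit():
            return int(t)
        if isinstance(t, (int, np.integer, float)) and not isinstance(t, bool):
            return int(t)
        return t

    ret = parcels["real_estate_type"].apply(_norm)
    res = ret.apply(lambda t: t in RESIDENTIAL_TYPES).to_numpy(bool)

    known = ret.apply(
        lambda t: t in RESIDENTIAL_TYPES or (isinstance(t, str) and t.startswith("NONRES"))
    ).to_numpy(bool)
    if not known.all():
        bad = parcels.loc[~known, "real_estate_type"].unique()
        raise ValueError(f"unknown real_estate_type code(s): {list(bad)!r}")

    units = parcels["housing_units"].to_numpy(float)
    afford = parcels["affordable_housing"].to_numpy(bool)

    single = np.where(
        res,
        ret.to_numpy(object) == 1,
        (units < 2) & ~afford,
    )
    out = pd.DataFrame(index=parcels.index)
    out["residential"] = res
    out["housing_type"] = np.where(single, "single_family", "multifamily")
    return out
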