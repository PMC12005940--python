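"""Translate fitted coefficients into reported effect-modification quantities.

With theta1 the log-odds per 10 µg/m³ PM2.5 at AER = 0 and theta3 the
additional log-odds per 10 µg/m³ per unit (hour^-1) AER, the percent change
in mortality odds per 10 µg/m³ at AER = a is

    100 * (exp(theta1 + a * theta3) - 1),

with a delta-method standard error sqrt(V11 + a^2 V33 + 2 a V13) on the
log-odds scale and Wald 95% intervals exponentiated from there. The per-unit
interaction odds ratio exp(theta3) and the percent changes at two AER values
are mutually consistent through the same log-linear identity, which also
allows back-computing one from the others. Percent changes are conventionally
anchored at the 25th and 75th percentiles of the analysis dataset's AER
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clogit import FitResult

Z95 = 1.959963984540054

#: fallback AER anchors (hour^-1): study-population 25th/75th percentiles
DEFAULT_AER_PERCENTILES = (0.270, 0.854)


@dataclass(frozen=True)
class EffectEstimate:
    """Percent change in mortality odds per 10 µg/m³ PM2.5 at a given AER."""
    aer_value: float
    percent_change: float
    ci_low: float
    ci_high: float
    se_logscale: float


def _theta(fit: FitResult, pm: str = "pm10u", inter: str = "pm10u:aer"
           ) -> tuple[float, float, float, float, float]:
    t1 = fit.coef(pm)
    v11 = fit.cov(pm, pm)
    if inter in fit.names:
        t3 = fit.coef(inter)
        v33 = fit.cov(inter, inter)
        v13 = fit.cov(pm, inter)
    else:
        t3 = v33 = v13 = 0.0
    return t1, t3, v11, v33, v13


def percent_change_at(fit: FitResult, aer_value: float,
                      pm: str = "pm10u", inter: str = "pm10u:aer"
                      ) -> EffectEstimate:
    """Percent change per 10 µg/m³ PM2.5 at a given AER, with delta-method CI.

    Works for main-effect-only fits (the product term is then taken as 0 and
    the estimate is independent of the AER value). Negative AER is an error.
    """
    if aer_value < 0:
        raise ValueError("AER value must be nonnegative")
    t1, t3, v11, v33, v13 = _theta(fit, pm, inter)
    a = float(aer_value)
    eta = t1 + a * t3
    se = float(np.sqrt(v11 + a * a * v33 + 2 * a * v13))
    return EffectEstimate(
        aer_value=a,
        percent_change=100.0 * (np.exp(eta) - 1.0),
        ci_low=100.0 * (np.exp(eta - Z95 * se) - 1.0),
        ci_high=100.0 * (np.exp(eta + Z95 * se) - 1.0),
        se_logscale=se,
    )


def interaction_or(fit: FitResult, inter: str = "pm10u:aer"
                   ) -> tuple[float, float, float, float]:
    """Per-unit-AER interaction OR with Wald 95% CI and p-value."""
    if inter not in fit.names:
        raise ValueError("fit has no interaction term")
    t3 = fit.coef(inter)
    se = fit.se(inter)
    from scipy import stats
    p = float(2 * stats.norm.sf(abs(t3 / se)))
    return (float(np.exp(t3)), float(np.exp(t3 - Z95 * se)),
            float(np.exp(t3 + Z95 * se)), p)


# ---------------------------------------------------------------------------
# arithmetic between printed quantities
# ---------------------------------------------------------------------------

def interaction_or_from_percent_changes(pc_low: float, aer_low: float,
                                        pc_high: float, aer_high: float
                                        ) -> float:
    """Back-compute the per-unit-AER interaction OR from two percent changes.

    Inverts the log-linear identity: OR = exp((ln(1 + pc_high/100) -
    ln(1 + pc_low/100)) / (aer_high - aer_low)).
    """
    if aer_high == aer_low:
        raise ValueError("AER anchors must differ")
    num = np.log1p(pc_high / 100.0) - np.log1p(pc_low / 100.0)
    return float(np.exp(num / (aer_high - aer_low)))


def percent_change_from_or(pc_ref: float, aer_ref: float,
                           or_interaction: float, aer_target: float) -> float:
    """Forward-compute the percent change at another AER from the OR.

    Moves the reference percent change along the log-linear effect-
    modification line: pc(a) = 100*(exp(ln(1+pc_ref/100) +
    (a - a_ref)*ln(OR)) - 1).
    """
    eta = np.log1p(pc_ref / 100.0) + (aer_target - aer_ref) * np.log(
        or_interaction)
    return float(100.0 * (np.exp(eta) - 1.0))


def aer_percentiles(rows: pd.DataFrame, q: tuple[float, float] = (25.0, 75.0)
                    ) -> tuple[float, float]:
    """Empirical AER percentiles of an analysis dataset (one value per
    stratum; linear/type-7 interpolation)."""
    per_stratum = rows.groupby("person_id")["aer"].first()
    lo, hi = np.percentile(per_stratum.to_numpy(float), q)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# stratified summary table
# ---------------------------------------------------------------------------

def stratified_report(fits: dict, percentiles: dict | tuple | None = None
                      ) -> pd.DataFrame:
    """Summary table over analysis cells (season x cause x housing stratum).

    ``fits`` maps a cell key (any tuple or string) to a :class:`FitResult`
    fitted on that cell's subset, or None for an empty cell, which is
    reported as missing rather than fabricated. ``percentiles`` gives the
    (q1, q3) AER anchors — one global pair, or a dict per cell; defaults to
    the study-population anchors 0.270/0.854.
    """
    recs = []
    for key, fit in fits.items():
        name = key if isinstance(key, str) else "/".join(map(str, key))
        if isinstance(percentiles, dict):
            q1, q3 = percentiles.get(key, DEFAULT_AER_PERCENTILES)
        elif percentiles is not None:
            q1, q3 = percentiles
        else:
            q1, q3 = DEFAULT_AER_PERCENTILES
        if fit is None:
            recs.append({"cell": name, "aer_q1": q1, "aer_q3": q3,
                         "missing": True})
            continue
        lo = percent_change_at(fit, q1)
        hi = percent_change_at(fit, q3)
        has_inter = "pm10u:aer" in fit.names
        if has_inter:
            orr, olo, ohi, p = interaction_or(fit)
            stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
        else:
            orr = olo = ohi = p = np.nan
            stars = ""
        recs.append({
            "cell": name, "missing": False,
            "aer_q1": q1, "aer_q3": q3,
            "pc_q1": lo.percent_change, "pc_q1_low": lo.ci_low,
            "pc_q1_high": lo.ci_high,
            "pc_q3": hi.percent_change, "pc_q3_low": hi.ci_low,
            "pc_q3_high": hi.ci_high,
            "interaction_or": orr, "or_low": olo, "or_high": ohi,
            "p_interaction": p, "significance": stars,
            "n_strata": fit.n_strata,
        })
    return pd.DataFrame(recs)


def effect_curve(fit: FitResult, aer_grid: np.ndarray) -> pd.DataFrame:
    """Percent change vs AER on a grid, for external plotting."""
    ests = [percent_change_at(fit, a) for a in aer_grid]
    return pd.DataFrame({
        "aer": [e.aer_value for e in ests],
        "percent_change": [e.percent_change for e in ests],
        "ci_low": [e.ci_low for e in ests],
        "ci_high": [e.ci_high for e in ests],
    })
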