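"""Eligibility funnel and projection of cohort results to the US population.

The funnel starts from the annual number of NIS medical discharges meeting
the survey's inclusion criteria (no operating room, age >= 40, stay >= 2
days), applies the surveyed at-risk fraction, removes patients already
receiving guideline prophylaxis, and excludes those with recognised
contraindications to anticoagulation.  The remaining "eligible but
unprotected" patients are multiplied by the cohort model's unrounded
deaths-averted rate; one admission counts as one 30-day exposure.  All
arithmetic is exact/unrounded; rounding is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea import CEAResult
from .parameters import FunnelCounts, PopulationConstants

__all__ = [
    "FunnelCounts",
    "FunnelProjection",
    "ExtrapolationResult",
    "funnel_rates",
    "apply_funnel",
    "national_impact",
    "iqr_scenario",
    "funnel_report",
]


def funnel_rates(counts: FunnelCounts) -> dict[str, float]:
    """Stage-to-stage proportions of the eligibility funnel (exact ratios)."""
    if counts.enrolled == 0 or counts.medical_ward == 0 or counts.at_vte_risk == 0:
        raise ZeroDivisionError("funnel rates are undefined for zero denominators")
    return {
        "medical_ward": counts.medical_ward / counts.enrolled,
        "at_vte_risk": counts.at_vte_risk / counts.medical_ward,
        "receiving_prophylaxis": counts.receiving_prophylaxis / counts.at_vte_risk,
        "contraindicated": counts.contraindicated / counts.at_vte_risk,
    }


@dataclass(frozen=True)
class FunnelProjection:
    """The national funnel applied to the NIS denominator (unrounded)."""

    nis_total: float
    at_risk: float
    receiving: float
    not_receiving: float
    eligible_unprotected: float


def apply_funnel(
    nis_total: float,
    at_risk_fraction: float,
    receiving_fraction: float,
    contraindicated_fraction: float,
) -> FunnelProjection:
    """Project the funnel fractions onto the national discharge total."""
    for name, f in (
        ("at_risk_fraction", at_risk_fraction),
        ("receiving_fraction", receiving_fraction),
        ("contraindicated_fraction", contraindicated_fraction),
    ):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    at_risk = nis_total * at_risk_fraction
    receiving = at_risk * receiving_fraction
    not_receiving = at_risk - receiving
    eligible = not_receiving * (1.0 - contraindicated_fraction)
    return FunnelProjection(
        nis_total=nis_total,
        at_risk=at_risk,
        receiving=receiving,
        not_receiving=not_receiving,
        eligible_unprotected=eligible,
    )


@dataclass(frozen=True)
class ExtrapolationResult:
    """Annual national impact of closing the prophylaxis gap with one strategy."""

    strategy_id: str
    eligible_unprotected: float
    deaths_averted_total: float
    cost_saved_total: float
    deaths_averted_per_1pct: float
    cost_saved_per_1pct: float
    flag: str = "ok"  # ok | dominated_or_equivalent


def national_impact(
    eligible_unprotected: float, cea: CEAResult, cohort_size: int
) -> ExtrapolationResult:
    """Scale a cohort CEA result to the eligible-unprotected population.

    Totals use the unrounded per-patient deaths-averted rate; cost savings
    are the deaths averted times the (absolute) savings per death averted,
    i.e. the eligible population times the per-patient saving.  A strategy
    that averts no deaths gets zero totals and an explanatory flag.
    """
    if cea.deaths_averted <= 0:
        return ExtrapolationResult(
            strategy_id=cea.strategy_id,
            eligible_unprotected=eligible_unprotected,
            deaths_averted_total=0.0,
            cost_saved_total=0.0,
            deaths_averted_per_1pct=0.0,
            cost_saved_per_1pct=0.0,
            flag="dominated_or_equivalent",
        )
    rate = cea.deaths_averted / cohort_size
    deaths_total = eligible_unprotected * rate
    cost_total = deaths_total * abs(cea.cost_per_death_averted) if cea.incremental_cost < 0 else 0.0
    return ExtrapolationResult(
        strategy_id=cea.strategy_id,
        eligible_unprotected=eligible_unprotected,
        deaths_averted_total=deaths_total,
        cost_saved_total=cost_total,
        deaths_averted_per_1pct=deaths_total / 100.0,
        cost_saved_per_1pct=cost_total / 100.0,
    )


def iqr_scenario(
    at_risk_range: tuple[float, float],
    cea_by_strategy: dict[str, CEAResult],
    population: PopulationConstants,
    receiving_fraction: float,
    contraindicated_fraction: float,
) -> dict[str, tuple[ExtrapolationResult, ExtrapolationResult]]:
    """National impact at the low/high ends of the at-risk-fraction IQR.

    Reruns the funnel and the national projection at each endpoint with all
    other fractions at base; every result field is linear in the at-risk
    fraction, so the endpoints bound the whole interval.
    """
    lo, hi = at_risk_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("at_risk_range must satisfy 0 <= low <= high <= 1")
    out: dict[str, tuple[ExtrapolationResult, ExtrapolationResult]] = {}
    for sid, cea in cea_by_strategy.items():
        endpoints = []
        for f in (lo, hi):
            proj = apply_funnel(
                population.nis_eligible_total, f, receiving_fraction, contraindicated_fraction
            )
            endpoints.append(
                national_impact(proj.eligible_unprotected, cea, population.cohort_size)
            )
        out[sid] = (endpoints[0], endpoints[1])
    return out


def funnel_report(counts: FunnelCounts, projection: FunnelProjection) -> str:
    """Human-readable funnel summary (survey counts and national projection)."""
    r = funnel_rates(counts)
    lines = [
        "Eligibility funnel (survey arm -> national projection)",
        f"  enrolled inpatients:            {counts.enrolled:>12,}",
        f"  in medical wards:               {counts.medical_ward:>12,}  ({100*r['medical_ward']:.1f}%)",
        f"  at VTE risk:                    {counts.at_vte_risk:>12,}  ({100*r['at_vte_risk']:.1f}%)",
        f"  receiving prophylaxis:          {counts.receiving_prophylaxis:>12,}  ({100*r['receiving_prophylaxis']:.1f}%)",
        f"  contraindicated (of at-risk):   {counts.contraindicated:>12,}  ({100*r['contraindicated']:.1f}%)",
        "",
        f"  national eligible discharges:   {projection.nis_total:>14,.0f}",
        f"  at VTE risk:                    {projection.at_risk:>14,.0f}",
        f"  receiving prophylaxis:          {projection.receiving:>14,.0f}",
        f"  not receiving:                  {projection.not_receiving:>14,.0f}",
        f"  eligible but unprotected:       {projection.eligible_unprotected:>14,.0f}",
    ]
    return "\n".join(lines)


def impact_frame(results: dict[str, ExtrapolationResult]) -> pd.DataFrame:
    rows = []
    for sid, r in results.items():
        rows.append(
            {
                "strategy": sid,
                "eligible_unprotected": r.eligible_unprotected,
                "deaths_averted_total": r.deaths_averted_total,
                "cost_saved_total": r.cost_saved_total,
                "deaths_averted_per_1pct": r.deaths_averted_per_1pct,
                "cost_saved_per_1pct": r.cost_saved_per_1pct,
                "flag": r.flag,
            }
        )
    return pd.DataFrame(rows)
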