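"""Incremental cost-effectiveness versus a comparator.

Sign convention: a negative incremental cost is a saving, so a dominant
strategy (cheaper and life-saving) has a negative cost per death averted.
All quantities are kept unrounded; rounding happens only in report writers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tree import CohortOutcome

__all__ = ["CEAResult", "compare", "death_rate_reduction_percent"]


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of one strategy against a comparator."""

    strategy_id: str
    comparator_id: str
    incremental_cost: float
    deaths_averted: float
    cost_per_death_averted: float | None
    dominance: str  # dominant | dominated | tradeoff | equivalent
    death_rate_reduction: float

    @property
    def icer(self) -> float | None:
        """Alias: the incremental cost-effectiveness ratio ($ per death averted)."""
        return self.cost_per_death_averted


def compare(strategy_outcome: CohortOutcome, comparator_outcome: CohortOutcome) -> CEAResult:
    """Incremental cost, deaths averted and ICER of a strategy vs a comparator.

    Both outcomes must refer to the same cohort size.  When the strategies
    avert exactly zero deaths the ratio is undefined (``None``) and the
    comparison is classified ``equivalent``.
    """
    if strategy_outcome.cohort_size != comparator_outcome.cohort_size:
        raise ValueError(
            "cohort sizes differ: "
            f"{strategy_outcome.cohort_size} vs {comparator_outcome.cohort_size}"
        )
    inc_cost = strategy_outcome.expected_total_cost - comparator_outcome.expected_total_cost
    averted = comparator_outcome.expected_deaths - strategy_outcome.expected_deaths
    if averted == 0.0:
        ratio = None
        dominance = "equivalent"
    else:
        ratio = inc_cost / averted
        if inc_cost < 0 and averted > 0:
            dominance = "dominant"
        elif inc_cost > 0 and averted < 0:
            dominance = "dominated"
        else:
            dominance = "tradeoff"
    return CEAResult(
        strategy_id=strategy_outcome.strategy_id,
        comparator_id=comparator_outcome.strategy_id,
        incremental_cost=inc_cost,
        deaths_averted=averted,
        cost_per_death_averted=ratio,
        dominance=dominance,
        death_rate_reduction=averted / strategy_outcome.cohort_size,
    )


def death_rate_reduction_percent(result: CEAResult, decimals: int = 1) -> float:
    """The cohort death-rate reduction as a percentage (one decimal by default)."""
    return round(100.0 * result.death_rate_reduction, decimals)
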