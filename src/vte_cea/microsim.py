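"""Synthetic data: patient-level microsimulation and admission records.

Two generators, both fully seeded:

* :func:`simulate_cohort` walks individual patients through a strategy tree,
  sampling each branch — a stochastic twin of the analytic expectation used
  to cross-validate :func:`vte_cea.tree.evaluate_tree`;
* :func:`generate_admissions` draws hospital-discharge-like records (age,
  length of stay, operating-room flag, risk diagnosis, prophylaxis and
  contraindication flags) so the eligibility filters can be exercised
  end-to-end against known marginals.

The admission generator is deliberately parametric and simple (truncated
normal age, geometric stay); only the filter thresholds and the configured
marginal fractions matter for correctness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import FunnelCounts
from .tree import CohortOutcome, TreeNode

__all__ = [
    "SimulatedCohort",
    "MixConfig",
    "ACCP_RISK_CATEGORIES",
    "simulate_cohort",
    "generate_admissions",
    "apply_endorse_filters",
]

#: diagnosis groups conferring guideline-defined VTE risk; carried as a
#: label for realism, never branched on.
ACCP_RISK_CATEGORIES = (
    "heart_failure",
    "respiratory_failure",
    "sepsis",
    "pneumonia",
    "cancer",
    "stroke",
    "acute_mi",
    "nonsurgical_trauma",
    "arthropathy_spondylopathy",
    "paralysis_coma",
)


@dataclass(frozen=True)
class SimulatedCohort:
    """Patient-level records plus the empirical analogue of a CohortOutcome."""

    records: pd.DataFrame
    outcome: CohortOutcome
    death_rate_se: float
    mean_cost_se: float


def simulate_cohort(
    root: TreeNode,
    n: int,
    seed: int | None = None,
    record_paths: bool = True,
) -> SimulatedCohort:
    """Walk ``n`` patients through the tree, sampling every branch.

    Traversal is breadth-wise over the set of occupied nodes, drawing one
    uniform per patient per branching, so the walk is a genuine stochastic
    simulation independent of the analytic expectation.  With
    ``record_paths=False`` the (memory-hungry) per-patient label trail is
    skipped — recommended beyond ~10^5 patients.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    strategy_id = root.label.split(":", 1)[1] if ":" in root.label else root.label

    cost = np.full(n, root.cost, dtype=float)
    died = np.zeros(n, dtype=bool)
    cause = np.full(n, "none", dtype=object)
    paths = np.full(n, root.label, dtype=object) if record_paths else None

    frontier: list[tuple[TreeNode, np.ndarray]] = [(root, np.arange(n))]
    while frontier:
        next_frontier: dict[int, tuple[TreeNode, list[np.ndarray]]] = {}
        for node, idx in frontier:
            if node.is_leaf:
                if node.is_death:
                    died[idx] = True
                    cause[idx] = node.death_cause
                continue
            probs = np.array([p for p, _ in node.children])
            edges = np.cumsum(probs)
            edges[-1] = max(edges[-1], 1.0)  # guard fp round-down
            draws = rng.random(idx.size)
            choice = np.searchsorted(edges, draws, side="right")
            for j, (_, child) in enumerate(node.children):
                sub = idx[choice == j]
                if sub.size == 0:
                    continue
                cost[sub] += child.cost
                if record_paths:
                    paths[sub] = paths[sub] + ("/" + child.label)
                key = id(child)
                if key in next_frontier:
                    next_frontier[key][1].append(sub)
                else:
                    next_frontier[key] = (child, [sub])
        frontier = [
            (node, np.concatenate(chunks) if len(chunks) > 1 else chunks[0])
            for node, chunks in next_frontier.values()
        ]

    records = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "strategy_id": strategy_id,
            "path": paths if record_paths else "",
            "died": died,
            "death_cause": cause,
            "accrued_cost": cost,
        }
    )
    death_rate = died.mean()
    by_cause = records.loc[died].groupby("death_cause", observed=True).size()
    outcome = CohortOutcome(
        strategy_id=strategy_id,
        cohort_size=n,
        expected_deaths=float(died.sum()),
        deaths_by_cause={k: float(v) for k, v in by_cause.items()},
        expected_total_cost=float(cost.sum()),
        cost_per_patient=float(cost.mean()),
    )
    return SimulatedCohort(
        records=records,
        outcome=outcome,
        death_rate_se=float(np.sqrt(death_rate * (1 - death_rate) / n)),
        mean_cost_se=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
    )


@dataclass(frozen=True)
class MixConfig:
    """Marginals of the synthetic admission mix.

    Defaults mirror the US survey arm: 43.9% of enrolled inpatients were
    surgical (operating room), 52.3% of eligible medical patients were at
    guideline-defined VTE risk, 47.5% of those received recommended
    prophylaxis and 12.2% had a recognised contraindication.  Age and stay
    are simple parametric stand-ins for an acutely ill medical population.
    """

    surgical_fraction: float = 0.439
    age_mean: float = 65.0
    age_sd: float = 15.0
    los_mean: float = 5.0
    at_risk_fraction: float = 0.523
    prophylaxis_fraction: float = 0.475
    contraindicated_fraction: float = 0.122

    def validate(self) -> None:
        for name in (
            "surgical_fraction",
            "at_risk_fraction",
            "prophylaxis_fraction",
            "contraindicated_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.age_sd <= 0 or self.los_mean < 1.0:
            raise ValueError("age_sd must be > 0 and los_mean >= 1")


def generate_admissions(
    n: int, mix_config: MixConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Draw ``n`` synthetic admission records from the configured marginals.

    All attributes are drawn independently; the risk/prophylaxis/
    contraindication flags are therefore Bernoulli with the configured
    probability in every subgroup, which is exactly what the funnel filters
    condition on.  Length of stay is geometric (support >= 1 day), age a
    truncated normal (>= 18 years).
    """
    mix = mix_config or MixConfig()
    mix.validate()
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(
            columns=[
                "admission_id",
                "age",
                "length_of_stay",
                "went_to_operating_room",
                "vte_risk_diagnosis",
                "risk_category",
                "contraindicated",
                "received_prophylaxis",
            ]
        )
    a = (18.0 - mix.age_mean) / mix.age_sd
    age = stats.truncnorm.rvs(a, np.inf, loc=mix.age_mean, scale=mix.age_sd, size=n, random_state=rng)
    los = rng.geometric(1.0 / mix.los_mean, size=n)
    at_risk = rng.random(n) < mix.at_risk_fraction
    category = np.where(
        at_risk, rng.choice(ACCP_RISK_CATEGORIES, size=n), "none"
    )
    return pd.DataFrame(
        {
            "admission_id": np.arange(n),
            "age": age,
            "length_of_stay": los.astype(int),
            "went_to_operating_room": rng.random(n) < mix.surgical_fraction,
            "vte_risk_diagnosis": at_risk,
            "risk_category": category,
            "contraindicated": rng.random(n) < mix.contraindicated_fraction,
            "received_prophylaxis": rng.random(n) < mix.prophylaxis_fraction,
        }
    )


def apply_endorse_filters(records: pd.DataFrame) -> FunnelCounts:
    """Tally the eligibility funnel over admission records.

    Filters, in order: not taken to the operating room (medical); age >= 40
    and length of stay >= 2 days (eligibility screen, both inclusive);
    risk-conferring diagnosis (at risk); receiving prophylaxis.
    Contraindications are tallied among the at-risk.  A pure function of the
    record set — row order is irrelevant.
    """
    if len(records) == 0:
        return FunnelCounts(0, 0, 0, 0, 0, age_los_eligible=0)
    medical = ~records["went_to_operating_room"].to_numpy(dtype=bool)
    eligible = medical & (records["age"].to_numpy() >= 40.0) & (
        records["length_of_stay"].to_numpy() >= 2
    )
    at_risk = eligible & records["vte_risk_diagnosis"].to_numpy(dtype=bool)
    receiving = at_risk & records["received_prophylaxis"].to_numpy(dtype=bool)
    contraindicated = at_risk & records["contraindicated"].to_numpy(dtype=bool)
    return FunnelCounts(
        enrolled=int(len(records)),
        medical_ward=int(medical.sum()),
        at_vte_risk=int(at_risk.sum()),
        receiving_prophylaxis=int(receiving.sum()),
        contraindicated=int(contraindicated.sum()),
        age_los_eligible=int(eligible.sum()),
    )
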