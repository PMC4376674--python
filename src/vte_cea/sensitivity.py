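"""One-way (threshold) and probabilistic sensitivity analysis.

One-way scans rebuild and re-evaluate the full decision tree at each grid
value of a single parameter, all else held at base case; thresholds are
found by bisection on a named, monotone criterion.

The probabilistic sensitivity analysis (PSA) redraws every probability from
a beta distribution (``alpha = p*n``, ``beta = (1-p)*n`` for an effective
sample size ``n``) and every unit cost from a gamma distribution
(``shape = 1/cv**2``, ``scale = mean*cv**2``), evaluates all three strategy
trees per draw, and summarises costs and deaths by percentiles.  Spreads
are not part of the published point estimates and are therefore explicit,
overridable inputs; see docs/methods.md for the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import CEAResult, compare
from .parameters import ParameterBundle, SharedParams, StrategyParams, validate_parameters
from .tree import CohortOutcome, build_all_trees, evaluate_tree

__all__ = [
    "OneWayScan",
    "ThresholdResult",
    "PSASample",
    "PSAResult",
    "CEACCurve",
    "ACTIVE_STRATEGIES",
    "get_parameter",
    "set_parameter",
    "one_way_scan",
    "find_threshold",
    "NonMonotoneCriterionError",
    "default_spread_config",
    "sample_psa_bundle",
    "run_psa",
    "build_ceac",
]

ACTIVE_STRATEGIES = ("LMWH", "UFH")
COMPARATOR = "NONE"

# ---------------------------------------------------------------------------
# parameter addressing


def _split_name(bundle: ParameterBundle, name: str) -> tuple[str, str]:
    scope, _, field_name = name.partition(".")
    if not field_name:
        raise KeyError(f"parameter name {name!r} must be '<scope>.<field>'")
    if scope not in ("shared", "costs") and scope not in bundle.strategies:
        raise KeyError(f"unknown parameter scope {scope!r} in {name!r}")
    return scope, field_name


def get_parameter(bundle: ParameterBundle, name: str) -> float:
    """Read one addressable parameter, e.g. ``"shared.p_dvt"`` is invalid but
    ``"shared.p_pe_given_untreated_dvt"``, ``"costs.treated_dvt"`` or
    ``"LMWH.p_dvt"`` are valid addresses."""
    scope, field_name = _split_name(bundle, name)
    target = {"shared": bundle.shared, "costs": bundle.costs}.get(scope, bundle.strategies.get(scope))
    if not hasattr(target, field_name):
        raise KeyError(f"unknown parameter {name!r}")
    return getattr(target, field_name)


def set_parameter(bundle: ParameterBundle, name: str, value: float) -> ParameterBundle:
    """Return a new bundle with one parameter replaced (validated)."""
    scope, field_name = _split_name(bundle, name)
    if scope == "shared":
        if not hasattr(bundle.shared, field_name):
            raise KeyError(f"unknown parameter {name!r}")
        new = replace(bundle, shared=replace(bundle.shared, **{field_name: value}))
    elif scope == "costs":
        if not hasattr(bundle.costs, field_name):
            raise KeyError(f"unknown parameter {name!r}")
        new = replace(bundle, costs=replace(bundle.costs, **{field_name: value}))
    else:
        sp = bundle.strategies[scope]
        if not hasattr(sp, field_name):
            raise KeyError(f"unknown parameter {name!r}")
        strategies = dict(bundle.strategies)
        strategies[scope] = replace(sp, **{field_name: value})
        new = replace(bundle, strategies=strategies)
    violations = validate_parameters(new)
    if violations:
        detail = "; ".join(str(v) for v in violations)
        raise ValueError(f"setting {name}={value!r} produces an invalid bundle: {detail}")
    return new


# ---------------------------------------------------------------------------
# one-way sensitivity


@dataclass(frozen=True)
class OneWayScan:
    """Outcomes of all strategies along a grid of one parameter."""

    parameter_name: str
    grid: tuple[float, ...]
    outcomes: Mapping[str, tuple[CohortOutcome, ...]]
    cea: Mapping[str, tuple[CEAResult, ...]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, x in enumerate(self.grid):
            for sid, outs in self.outcomes.items():
                o = outs[i]
                r = self.cea[sid][i] if sid in self.cea else None
                rows.append(
                    {
                        "parameter": self.parameter_name,
                        "value": x,
                        "strategy": sid,
                        "deaths": o.expected_deaths,
                        "total_cost": o.expected_total_cost,
                        "incremental_cost": r.incremental_cost if r else np.nan,
                        "deaths_averted": r.deaths_averted if r else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def _evaluate_bundle(bundle: ParameterBundle, cohort_size: int | None = None) -> dict[str, CohortOutcome]:
    n = cohort_size or bundle.population.cohort_size
    trees = build_all_trees(bundle)
    return {sid: evaluate_tree(tree, n, sid) for sid, tree in trees.items()}


def one_way_scan(
    parameter_name: str,
    grid: Sequence[float],
    bundle: ParameterBundle,
    cohort_size: int | None = None,
) -> OneWayScan:
    """Re-evaluate the model along ``grid`` values of one parameter."""
    grid = tuple(float(g) for g in grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    outcomes: dict[str, list[CohortOutcome]] = {}
    cea: dict[str, list[CEAResult]] = {s: [] for s in ACTIVE_STRATEGIES}
    for x in grid:
        outs = _evaluate_bundle(set_parameter(bundle, parameter_name, x), cohort_size)
        for sid, o in outs.items():
            outcomes.setdefault(sid, []).append(o)
        for sid in ACTIVE_STRATEGIES:
            cea[sid].append(compare(outs[sid], outs[COMPARATOR]))
    return OneWayScan(
        parameter_name=parameter_name,
        grid=grid,
        outcomes={sid: tuple(v) for sid, v in outcomes.items()},
        cea={sid: tuple(v) for sid, v in cea.items()},
    )


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a threshold search: the crossing value, or why there is none."""

    parameter_name: str
    criterion: str
    value: float | None
    status: str  # found | always_satisfied | never_satisfied


class NonMonotoneCriterionError(RuntimeError):
    """The criterion changes truth value more than once over the bounds."""


def _criterion_predicate(criterion: str) -> Callable[[dict[str, CEAResult]], bool]:
    """Resolve a named criterion to a predicate over per-strategy CEA results.

    Supported names: ``cost_saving:<S>``, ``both_cost_saving``,
    ``dominant:<S>`` (cost-saving and life-saving) and ``both_dominant``.
    """

    def cost_saving(r: CEAResult) -> bool:
        return r.incremental_cost <= 0

    def dominant(r: CEAResult) -> bool:
        return r.incremental_cost <= 0 and r.deaths_averted >= 0

    if criterion == "both_cost_saving":
        return lambda res: all(cost_saving(res[s]) for s in ACTIVE_STRATEGIES)
    if criterion == "both_dominant":
        return lambda res: all(dominant(res[s]) for s in ACTIVE_STRATEGIES)
    kind, _, sid = criterion.partition(":")
    if sid in ACTIVE_STRATEGIES and kind in ("cost_saving", "dominant"):
        fn = cost_saving if kind == "cost_saving" else dominant
        return lambda res, fn=fn, sid=sid: fn(res[sid])
    raise KeyError(f"unknown criterion {criterion!r}")


def find_threshold(
    parameter_name: str,
    criterion: str,
    bounds: tuple[float, float],
    bundle: ParameterBundle,
    tol: float = 1e-4,
    monotonicity_grid: int = 9,
) -> ThresholdResult:
    """Bisect for the parameter value at which ``criterion`` changes truth.

    The criterion must be monotone over ``bounds``; this is checked on a
    coarse grid (``monotonicity_grid`` interior points) and a violation is
    reported as :class:`NonMonotoneCriterionError` rather than silently
    answered.  If the criterion holds (or fails) at both bounds the result
    carries status ``always_satisfied`` (or ``never_satisfied``).
    """
    predicate = _criterion_predicate(criterion)
    lo, hi = float(bounds[0]), float(bounds[1])
    if lo >= hi:
        raise ValueError("bounds must satisfy low < high")

    def truth(x: float) -> bool:
        outs = _evaluate_bundle(set_parameter(bundle, parameter_name, x))
        return predicate({s: compare(outs[s], outs[COMPARATOR]) for s in ACTIVE_STRATEGIES})

    t_lo, t_hi = truth(lo), truth(hi)
    probe = [truth(x) for x in np.linspace(lo, hi, monotonicity_grid + 2)[1:-1]]
    flips = sum(a != b for a, b in zip([t_lo] + probe, probe + [t_hi]))
    if flips > 1:
        raise NonMonotoneCriterionError(
            f"criterion {criterion!r} is not monotone in {parameter_name!r} over {bounds}"
        )
    if t_lo == t_hi:
        status = "always_satisfied" if t_lo else "never_satisfied"
        return ThresholdResult(parameter_name, criterion, None, status)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if truth(mid) == t_lo:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(parameter_name, criterion, 0.5 * (lo + hi), "found")


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

#: spread entries: {"ess": n} (beta), {"cv": c} (gamma) or {"fixed": True}
SpreadConfig = Mapping[str, Mapping[str, float | bool]]

# Effective sample sizes reflecting the scale of the source evidence: the
# prophylaxis efficacy/safety rows come from a randomized trial with a few
# hundred evaluable patients per arm; the shared clinical probabilities from
# cohort studies of broadly similar size.  Costs get a coefficient of
# variation of 0.25.  All overridable per parameter.
DEFAULT_STRATEGY_ESS = 400.0
DEFAULT_SHARED_ESS = 150.0
DEFAULT_COST_CV = 0.25

_SAMPLED_STRATEGY_FIELDS = ("p_dvt", "p_bleed", "p_hit")
# pe_scan_avg_* are derived from the sampled CT and V/Q rows, never drawn
_DERIVED_SHARED = ("pe_scan_avg_sens", "pe_scan_avg_spec")


def _shared_prob_fields(shared: SharedParams) -> list[str]:
    from dataclasses import fields as dc_fields

    out = []
    for f in dc_fields(SharedParams):
        if f.name in _DERIVED_SHARED:
            continue
        if getattr(shared, f.name) is None:
            continue
        out.append(f.name)
    return out


def default_spread_config(bundle: ParameterBundle) -> dict[str, dict]:
    """The shipped spread configuration (see module docstring for rationale)."""
    config: dict[str, dict] = {}
    for sid, sp in bundle.strategies.items():
        for field_name in _SAMPLED_STRATEGY_FIELDS:
            config[f"{sid}.{field_name}"] = {"ess": DEFAULT_STRATEGY_ESS}
    for field_name in _shared_prob_fields(bundle.shared):
        config[f"shared.{field_name}"] = {"ess": DEFAULT_SHARED_ESS}
    from dataclasses import fields as dc_fields

    from .parameters import CostTable

    for f in dc_fields(CostTable):
        config[f"costs.{f.name}"] = {"cv": DEFAULT_COST_CV}
    return config


def _draw_prob(rng: np.random.Generator, p: float, entry: Mapping) -> float:
    if entry.get("fixed") or p in (0.0, 1.0):
        return p  # structural zero/one: never sampled
    ess = float(entry["ess"])
    if ess <= 0:
        return p
    return float(rng.beta(p * ess, (1.0 - p) * ess))


def _draw_cost(rng: np.random.Generator, mean: float, entry: Mapping) -> float:
    if entry.get("fixed") or mean == 0.0:
        return mean
    cv = float(entry["cv"])
    if cv <= 0:
        return mean
    shape = 1.0 / cv**2
    scale = mean * cv**2
    return float(rng.gamma(shape, scale))


def sample_psa_bundle(
    bundle: ParameterBundle,
    spread_config: SpreadConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> ParameterBundle:
    """Draw one parameter bundle from the PSA distributions.

    Probabilities are beta-distributed, costs gamma-distributed; structural
    zeros (e.g. HIT without heparin exposure) and zero-spread entries stay at
    their base value.  ``rng`` may be a Generator or a seed.  Draws follow a
    fixed canonical parameter order, so equal seeds give equal bundles.
    """
    if spread_config is None:
        spread_config = default_spread_config(bundle)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def entry(name: str) -> Mapping:
        try:
            return spread_config[name]
        except KeyError:
            raise KeyError(f"spread_config is missing an entry for {name!r}") from None

    strategies: dict[str, StrategyParams] = {}
    for sid in sorted(bundle.strategies):
        sp = bundle.strategies[sid]
        draws = {
            fn: _draw_prob(rng, getattr(sp, fn), entry(f"{sid}.{fn}"))
            for fn in _SAMPLED_STRATEGY_FIELDS
        }
        # mutually exclusive AEs: renormalise the (astronomically rare) overflow
        if draws["p_bleed"] + draws["p_hit"] > 1.0:
            total = draws["p_bleed"] + draws["p_hit"]
            draws["p_bleed"] /= total
            draws["p_hit"] /= total
        strategies[sid] = replace(sp, **draws)

    shared_draws = {
        fn: _draw_prob(rng, getattr(bundle.shared, fn), entry(f"shared.{fn}"))
        for fn in _shared_prob_fields(bundle.shared)
    }
    shared = replace(bundle.shared, **shared_draws)
    # keep the averaged-scan invariant; skip when nothing was redrawn so a
    # zero-spread sample reproduces the base bundle bit-for-bit
    base = bundle.shared
    if shared.pe_ct_sens is not None and shared.pe_vq_sens is not None:
        if (shared.pe_ct_sens, shared.pe_vq_sens) != (base.pe_ct_sens, base.pe_vq_sens):
            shared = replace(shared, pe_scan_avg_sens=(shared.pe_ct_sens + shared.pe_vq_sens) / 2.0)
    if shared.pe_ct_spec is not None and shared.pe_vq_spec is not None:
        if (shared.pe_ct_spec, shared.pe_vq_spec) != (base.pe_ct_spec, base.pe_vq_spec):
            shared = replace(shared, pe_scan_avg_spec=(shared.pe_ct_spec + shared.pe_vq_spec) / 2.0)

    from dataclasses import fields as dc_fields

    from .parameters import CostTable

    cost_draws = {
        f.name: _draw_cost(rng, getattr(bundle.costs, f.name), entry(f"costs.{f.name}"))
        for f in dc_fields(CostTable)
    }
    costs = replace(bundle.costs, **cost_draws)
    return replace(bundle, strategies=strategies, shared=shared, costs=costs)


@dataclass(frozen=True)
class PSASample:
    """One PSA iteration: the sampled bundle and its evaluated outcomes."""

    index: int
    bundle: ParameterBundle
    outcomes: Mapping[str, CohortOutcome]
    cea: Mapping[str, CEAResult]


@dataclass(frozen=True)
class PSAResult:
    """All PSA iterations plus a percentile summary per strategy."""

    samples: tuple[PSASample, ...]
    summary: pd.DataFrame
    seed: int | None

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            for sid, o in s.outcomes.items():
                rows.append(
                    {
                        "iteration": s.index,
                        "strategy": sid,
                        "deaths": o.expected_deaths,
                        "total_cost": o.expected_total_cost,
                    }
                )
        return pd.DataFrame(rows)


def run_psa(
    bundle: ParameterBundle,
    spread_config: SpreadConfig | None = None,
    n_iter: int = 10_000,
    seed: int | None = None,
    cohort_size: int | None = None,
) -> PSAResult:
    """Monte Carlo PSA: ``n_iter`` full tree evaluations on sampled bundles.

    Reproducible end-to-end from ``seed``: each iteration draws from its own
    deterministic substream, so results do not depend on evaluation order.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if spread_config is None:
        spread_config = default_spread_config(bundle)
    n = cohort_size or bundle.population.cohort_size
    streams = np.random.SeedSequence(seed).spawn(n_iter)
    samples: list[PSASample] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        drawn = sample_psa_bundle(bundle, spread_config, rng)
        trees = build_all_trees(drawn)
        outcomes = {sid: evaluate_tree(tree, n, sid) for sid, tree in trees.items()}
        cea = {sid: compare(outcomes[sid], outcomes[COMPARATOR]) for sid in ACTIVE_STRATEGIES}
        samples.append(PSASample(index=i, bundle=drawn, outcomes=outcomes, cea=cea))

    rows = []
    for sid in bundle.strategies:
        deaths = np.array([s.outcomes[sid].expected_deaths for s in samples])
        cost = np.array([s.outcomes[sid].expected_total_cost for s in samples])
        for q, tag in ((2.5, "low_2.5"), (50.0, "median"), (97.5, "high_97.5")):
            rows.append(
                {
                    "strategy": sid,
                    "quantile": tag,
                    "deaths": float(np.percentile(deaths, q)),
                    "total_cost": float(np.percentile(cost, q)),
                }
            )
    summary = pd.DataFrame(rows)
    return PSAResult(samples=tuple(samples), summary=summary, seed=seed)


# ---------------------------------------------------------------------------
# cost-effectiveness acceptability curve


@dataclass(frozen=True)
class CEACCurve:
    """P(strategy is optimal) against willingness to pay per death averted."""

    wtp_grid: tuple[float, ...]
    probabilities: Mapping[str, np.ndarray]  # strategy -> fraction per WTP

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, probs in self.probabilities.items():
            for wtp, p in zip(self.wtp_grid, probs):
                rows.append({"wtp": wtp, "strategy": sid, "probability": p})
        return pd.DataFrame(rows)


def build_ceac(samples: Iterable[PSASample], wtp_grid: Sequence[float]) -> CEACCurve:
    """Acceptability curve by net-monetary-benefit ranking.

    At willingness-to-pay ``lambda`` a strategy's net monetary benefit
    relative to no prophylaxis is ``lambda * deaths_averted -
    incremental_cost`` (zero for the comparator itself).  Ties go to the
    cheaper strategy; a full tie goes to the comparator.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty PSA sample set")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0 or np.any(wtp < 0) or np.any(np.diff(wtp) <= 0):
        raise ValueError("wtp_grid must be non-negative and strictly increasing")

    order = (COMPARATOR,) + ACTIVE_STRATEGIES  # comparator first for full ties
    n = len(samples)
    averted = np.zeros((n, len(order)))
    inc_cost = np.zeros((n, len(order)))
    for j, sid in enumerate(order[1:], start=1):
        averted[:, j] = [s.cea[sid].deaths_averted for s in samples]
        inc_cost[:, j] = [s.cea[sid].incremental_cost for s in samples]

    probabilities = {sid: np.zeros(wtp.size) for sid in order}
    for k, lam in enumerate(wtp):
        nmb = lam * averted - inc_cost
        best = nmb.max(axis=1, keepdims=True)
        tied = nmb >= best - 1e-9
        cost_among_tied = np.where(tied, inc_cost, np.inf)
        winner = np.argmin(cost_among_tied, axis=1)  # cheaper wins; comparator first
        for j, sid in enumerate(order):
            probabilities[sid][k] = np.mean(winner == j)
    return CEACCurve(wtp_grid=tuple(wtp.tolist()), probabilities=probabilities)
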