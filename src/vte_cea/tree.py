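"""Decision-tree construction and evaluation.

The model is a single-pass, 30-day decision tree for one hospital admission.
Per strategy (LMWH, UFH, no prophylaxis) the tree branches on:

1. prophylaxis-associated adverse events — bleed, HIT or neither, mutually
   exclusive; bleed splits into major (possibly fatal) and minor, HIT into
   symptomatic (possibly fatal) and asymptomatic; AE survivors face no
   further VTE risk;
2. for patients without an AE, incident DVT, followed by a clinical
   suspicion gate and ultrasound confirmation; confirmed DVT is treated
   (with its own bleed/HIT risk and a residual PE risk), unconfirmed or
   unsuspected DVT remains untreated with a much higher PE risk;
3. non-DVT patients can be false clinical positives (diagnosis cost) and
   false ultrasound positives (anticoagulated, with treatment AE risk);
4. any PE can be immediately fatal (sudden death); survivors pass a clinical
   suspicion gate and an averaged CT/V-Q scan.  The diagnostic cascade
   determines which patients accrue PE diagnosis and treatment costs.  PE
   case fatality, however, is governed by whether the antecedent DVT was
   treated: breakthrough PE on anticoagulation carries the treated-PE
   fatality, PE after untreated DVT carries the untreated-PE fatality.
   (This cost/fatality split is what reproduces the published base case and
   the published effectiveness threshold; see docs/methods.md.)
5. every patient who has not died of a modelled cause faces a terminal,
   independent underlying-illness death branch.

Costs accumulate additively along a path (no discounting over the 30-day
horizon); the prophylaxis course cost is attached to the root node.

Two independent evaluation routes are provided: recursive expectation
(:func:`evaluate_tree`) and exhaustive path enumeration
(:func:`enumerate_paths`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .parameters import (
    CostTable,
    ParameterBundle,
    SharedParams,
    StrategyParams,
    validate_parameters,
)

__all__ = [
    "TreeNode",
    "CohortOutcome",
    "DEATH_CAUSES",
    "build_tree",
    "build_all_trees",
    "evaluate_tree",
    "enumerate_paths",
    "tree_outline",
    "tree_to_dict",
    "InvalidTreeError",
]

#: Terminal causes of death recognised by the model.  "none" marks survival.
DEATH_CAUSES = (
    "major_bleed",
    "symptomatic_hit",
    "sudden_pe",
    "treated_pe",
    "untreated_pe",
    "false_positive_pe_tx",
    "dvt_tx_ae",
    "underlying",
    "none",
)

_PROB_TOL = 1e-12


class InvalidTreeError(ValueError):
    """The tree violates a structural invariant (e.g. branch mass != 1)."""


class TreeNode:
    """One node of the decision tree.

    ``cost`` is the incremental cost incurred on entering the node; the cost
    of a path is the sum over its nodes.  Internal nodes carry ``children``
    as ``(branch_probability, child)`` pairs summing to one; leaves carry a
    terminal payoff (``is_death`` and ``death_cause``).  Identical sub-trees
    may be shared between branches; evaluation and enumeration treat the
    structure as a tree of paths.
    """

    __slots__ = ("label", "cost", "children", "is_death", "death_cause")

    def __init__(
        self,
        label: str,
        cost: float = 0.0,
        children: list[tuple[float, "TreeNode"]] | None = None,
        is_death: bool = False,
        death_cause: str | None = None,
    ):
        self.label = label
        self.cost = float(cost)
        self.children = children or []
        self.is_death = is_death
        self.death_cause = death_cause
        if not self.children and death_cause is None:
            raise InvalidTreeError(f"leaf {label!r} has no terminal payoff")
        if self.children and death_cause is not None:
            raise InvalidTreeError(f"internal node {label!r} carries a terminal payoff")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def terminal_payoff(self) -> tuple[float, bool, str] | None:
        if not self.is_leaf:
            return None
        return (self.cost, self.is_death, self.death_cause)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"leaf:{self.death_cause}" if self.is_leaf else f"{len(self.children)} children"
        return f"TreeNode({self.label!r}, cost={self.cost:.0f}, {kind})"


def _check_tree(node: TreeNode, _seen: set[int] | None = None) -> None:
    seen = _seen if _seen is not None else set()
    if id(node) in seen:
        return
    seen.add(id(node))
    if node.is_leaf:
        if node.death_cause not in DEATH_CAUSES:
            raise InvalidTreeError(f"unknown death cause {node.death_cause!r} at {node.label!r}")
        if node.is_death != (node.death_cause != "none"):
            raise InvalidTreeError(f"leaf {node.label!r}: is_death inconsistent with cause")
        return
    total = 0.0
    for p, child in node.children:
        if not (0.0 <= p <= 1.0):
            raise InvalidTreeError(f"branch probability {p} out of [0,1] at {node.label!r}")
        total += p
        _check_tree(child, seen)
    if abs(total - 1.0) > _PROB_TOL:
        raise InvalidTreeError(f"branch probabilities at {node.label!r} sum to {total!r}, not 1")


@dataclass(frozen=True)
class CohortOutcome:
    """Expected deaths and costs for a cohort run through one strategy tree."""

    strategy_id: str
    cohort_size: int
    expected_deaths: float
    deaths_by_cause: dict[str, float] = field(compare=False)
    expected_total_cost: float = 0.0
    cost_per_patient: float = 0.0

    @property
    def death_rate(self) -> float:
        return self.expected_deaths / self.cohort_size


def _leaf(label: str, cause: str, cost: float = 0.0) -> TreeNode:
    return TreeNode(label, cost=cost, is_death=cause != "none", death_cause=cause)


def _fatal_or(label: str, p_death: float, cause: str, survivor: TreeNode, cost: float = 0.0) -> TreeNode:
    """A node whose occupant dies with ``p_death`` or continues to ``survivor``."""
    return TreeNode(
        label,
        cost=cost,
        children=[(p_death, _leaf(f"death_{cause}", cause)), (1.0 - p_death, survivor)],
    )


def build_tree(strategy: StrategyParams, shared: SharedParams, costs: CostTable) -> TreeNode:
    """Construct the decision tree for one prophylaxis strategy.

    The returned root carries the 7-day prophylaxis course cost; every other
    cost is attached where the corresponding service is rendered.  Raises
    :class:`InvalidTreeError` via construction if the inputs are degenerate;
    validate the full bundle with :func:`build_all_trees` or
    :func:`vte_cea.parameters.validate_parameters` first when in doubt.
    """
    s, c = shared, costs

    # terminal underlying-illness branch, shared by every surviving path
    underlying = _fatal_or("underlying_illness", s.p_death_underlying, "underlying", _leaf("survive", "none"))

    def severity_subtree(major_cause: str, hit_cause: str) -> tuple[TreeNode, TreeNode]:
        """Consequence sub-trees of a bleed and of HIT (shared costs/fatality)."""
        major = _fatal_or("major_bleed", s.p_death_given_major_bleed, major_cause, underlying, cost=c.major_bleed)
        minor = TreeNode("minor_bleed", cost=c.minor_bleed, children=[(1.0, underlying)])
        bleed = TreeNode(
            "bleed",
            children=[(s.p_major_given_bleed, major), (1.0 - s.p_major_given_bleed, minor)],
        )
        symp = _fatal_or(
            "symptomatic_hit", s.p_death_given_symptomatic_hit, hit_cause, underlying, cost=c.symptomatic_hit
        )
        asym = TreeNode("asymptomatic_hit", cost=c.asymptomatic_hit, children=[(1.0, underlying)])
        hit = TreeNode(
            "hit",
            children=[(s.p_symptomatic_given_hit, symp), (1.0 - s.p_symptomatic_given_hit, asym)],
        )
        return bleed, hit

    def pe_subtree(p_fatal: float, fatal_cause_treated: str) -> TreeNode:
        """A pulmonary embolism event.

        The diagnostic cascade (clinical suspicion, then averaged scan)
        decides who accrues diagnosis/treatment costs; ``p_fatal`` is the
        case fatality of every non-sudden-death path, set by the treatment
        status of the antecedent DVT.
        """
        treated = _fatal_or(
            "pe_confirmed_treated", p_fatal, fatal_cause_treated, underlying, cost=c.treated_pe
        )
        scan_negative = _fatal_or("pe_scan_negative", p_fatal, "untreated_pe", underlying)
        suspected = TreeNode(
            "pe_suspected",
            cost=c.pe_diagnosis,
            children=[(s.pe_scan_avg_sens, treated), (1.0 - s.pe_scan_avg_sens, scan_negative)],
        )
        unsuspected = _fatal_or("pe_not_suspected", p_fatal, "untreated_pe", underlying)
        survived_onset = TreeNode(
            "pe_survived_onset",
            children=[(s.pe_clin_sens, suspected), (1.0 - s.pe_clin_sens, unsuspected)],
        )
        return TreeNode(
            "pe",
            children=[
                (s.p_sudden_death_given_pe, _leaf("sudden_death", "sudden_pe")),
                (1.0 - s.p_sudden_death_given_pe, survived_onset),
            ],
        )

    def fp_pe_subtree() -> TreeNode:
        """False-positive PE workup of a DVT patient whose PE did not occur."""
        treated = _fatal_or(
            "pe_false_positive_treated",
            s.p_death_given_pe_tx_neg,
            "false_positive_pe_tx",
            underlying,
            cost=c.treated_pe,
        )
        suspected = TreeNode(
            "pe_false_suspected",
            cost=c.pe_diagnosis,
            children=[(1.0 - s.pe_scan_avg_spec, treated), (s.pe_scan_avg_spec, underlying)],
        )
        return TreeNode(
            "no_pe",
            children=[(1.0 - s.pe_clin_spec, suspected), (s.pe_clin_spec, underlying)],
        )

    fp_pe = fp_pe_subtree()
    pe_after_tx = pe_subtree(s.p_death_given_pe_tx_pos, "treated_pe")
    pe_after_untx = pe_subtree(s.p_death_given_untreated_pe, "treated_pe")

    tx_bleed, tx_hit = severity_subtree("dvt_tx_ae", "dvt_tx_ae")
    p_tx_ae = s.p_bleed_given_dvt_tx + s.p_hit_given_dvt_tx
    no_tx_ae = TreeNode(
        "no_tx_ae",
        children=[
            (s.p_pe_given_dvt_tx, pe_after_tx),
            (1.0 - s.p_pe_given_dvt_tx, fp_pe),
        ],
    )
    treated_dvt = TreeNode(
        "dvt_confirmed_treated",
        cost=c.treated_dvt,
        children=[
            (s.p_bleed_given_dvt_tx, tx_bleed),
            (s.p_hit_given_dvt_tx, tx_hit),
            (1.0 - p_tx_ae, no_tx_ae),
        ],
    )

    untreated_dvt = TreeNode(
        "dvt_untreated",
        children=[
            (s.p_pe_given_untreated_dvt, pe_after_untx),
            (1.0 - s.p_pe_given_untreated_dvt, fp_pe),
        ],
    )

    dvt_suspected = TreeNode(
        "dvt_suspected",
        cost=c.dvt_diagnosis,
        children=[(s.dvt_us_sens, treated_dvt), (1.0 - s.dvt_us_sens, untreated_dvt)],
    )
    dvt = TreeNode(
        "dvt",
        children=[(s.dvt_clin_sens, dvt_suspected), (1.0 - s.dvt_clin_sens, untreated_dvt)],
    )

    # false-positive DVT workup among patients without DVT
    no_fp_tx_ae = TreeNode("no_tx_ae", children=[(1.0, underlying)])
    fp_treated = TreeNode(
        "dvt_false_positive_treated",
        cost=c.treated_dvt,
        children=[
            (s.p_bleed_given_dvt_tx, tx_bleed),
            (s.p_hit_given_dvt_tx, tx_hit),
            (1.0 - p_tx_ae, no_fp_tx_ae),
        ],
    )
    fp_suspected = TreeNode(
        "dvt_false_suspected",
        cost=c.dvt_diagnosis,
        children=[(1.0 - s.dvt_us_spec, fp_treated), (s.dvt_us_spec, underlying)],
    )
    no_dvt = TreeNode(
        "no_dvt",
        children=[(1.0 - s.dvt_clin_spec, fp_suspected), (s.dvt_clin_spec, underlying)],
    )

    no_ae = TreeNode(
        "no_ae",
        children=[(strategy.p_dvt, dvt), (1.0 - strategy.p_dvt, no_dvt)],
    )

    ppx_bleed, ppx_hit = severity_subtree("major_bleed", "symptomatic_hit")
    root = TreeNode(
        f"admission:{strategy.strategy_id}",
        cost=strategy.prophylaxis_cost,
        children=[
            (strategy.p_bleed, ppx_bleed),
            (strategy.p_hit, ppx_hit),
            (1.0 - strategy.p_bleed - strategy.p_hit, no_ae),
        ],
    )
    _check_tree(root)
    return root


def build_all_trees(bundle: ParameterBundle) -> dict[str, TreeNode]:
    """Build one tree per strategy, refusing an invalid parameter bundle."""
    violations = validate_parameters(bundle)
    if violations:
        detail = "; ".join(str(v) for v in violations)
        raise InvalidTreeError(f"refusing to build trees from invalid parameters: {detail}")
    return {
        sid: build_tree(sp, bundle.shared, bundle.costs)
        for sid, sp in bundle.strategies.items()
    }


def evaluate_tree(root: TreeNode, cohort_size: int, strategy_id: str | None = None) -> CohortOutcome:
    """Expected deaths (by cause) and expected costs by recursive expectation.

    Shared sub-trees are memoised, so evaluation is linear in the number of
    distinct nodes rather than the number of paths.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    _check_tree(root)
    if strategy_id is None:
        strategy_id = root.label.split(":", 1)[1] if ":" in root.label else root.label

    memo: dict[int, tuple[float, dict[str, float]]] = {}

    def visit(node: TreeNode) -> tuple[float, dict[str, float]]:
        key = id(node)
        if key in memo:
            return memo[key]
        if node.is_leaf:
            result = (node.cost, {node.death_cause: 1.0} if node.is_death else {})
        else:
            cost = node.cost
            causes: dict[str, float] = {}
            for p, child in node.children:
                ccost, ccauses = visit(child)
                cost += p * ccost
                for cause, q in ccauses.items():
                    causes[cause] = causes.get(cause, 0.0) + p * q
            result = (cost, causes)
        memo[key] = result
        return result

    cost_per_patient, causes = visit(root)
    p_death = sum(causes.values())
    return CohortOutcome(
        strategy_id=strategy_id,
        cohort_size=cohort_size,
        expected_deaths=cohort_size * p_death,
        deaths_by_cause={cause: cohort_size * q for cause, q in sorted(causes.items())},
        expected_total_cost=cohort_size * cost_per_patient,
        cost_per_patient=cost_per_patient,
    )


def enumerate_paths(
    root: TreeNode, prune_zero: bool = False
) -> Iterator[tuple[float, float, bool, str, tuple[str, ...]]]:
    """Yield every terminal path as (probability, cost, is_death, cause, labels).

    An independent evaluation route: expectations over this sequence must
    reproduce :func:`evaluate_tree`.  With ``prune_zero`` branches of exactly
    zero probability are skipped (removing zero mass leaves expectations
    unchanged).
    """
    _check_tree(root)

    stack: list[tuple[TreeNode, float, float, tuple[str, ...]]] = [
        (root, 1.0, 0.0, ())
    ]
    while stack:
        node, prob, cost, labels = stack.pop()
        cost += node.cost
        labels = labels + (node.label,)
        if node.is_leaf:
            yield prob, cost, node.is_death, node.death_cause, labels
            continue
        for p, child in reversed(node.children):
            if prune_zero and p == 0.0:
                continue
            stack.append((child, prob * p, cost, labels))


def tree_outline(root: TreeNode, max_depth: int | None = None) -> str:
    """Plain-text indented outline of the tree for audit/diffing."""
    lines: list[str] = []

    def visit(node: TreeNode, prob: float | None, depth: int) -> None:
        if max_depth is not None and depth > max_depth:
            return
        prefix = "  " * depth
        ptxt = "" if prob is None else f"p={prob:g} "
        ctxt = f" +${node.cost:,.0f}" if node.cost else ""
        if node.is_leaf:
            outcome = f"DEATH[{node.death_cause}]" if node.is_death else "survive"
            lines.append(f"{prefix}{ptxt}{node.label}{ctxt} -> {outcome}")
        else:
            lines.append(f"{prefix}{ptxt}{node.label}{ctxt}")
            for p, child in node.children:
                visit(child, p, depth + 1)

    visit(root, None, 0)
    return "\n".join(lines)


def tree_to_dict(root: TreeNode) -> dict:
    """Machine-readable nested rendering (JSON-serialisable)."""
    out: dict = {"label": root.label, "cost": root.cost}
    if root.is_leaf:
        out["is_death"] = root.is_death
        out["death_cause"] = root.death_cause
    else:
        out["children"] = [
            {"probability": p, "node": tree_to_dict(child)} for p, child in root.children
        ]
    return out
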