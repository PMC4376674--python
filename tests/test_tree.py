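"""Tree construction, dual-route evaluation, and structural invariants."""

import math
from dataclasses import replace

import pytest
from hypothesis import given, strategies as st

from vte_cea.parameters import load_parameters
from vte_cea.tree import (
    InvalidTreeError,
    TreeNode,
    build_all_trees,
    build_tree,
    enumerate_paths,
    evaluate_tree,
    tree_outline,
    tree_to_dict,
)

STRATEGIES = ("NONE", "LMWH", "UFH")

# Terminal-path count per strategy tree, frozen once from the exhaustive
# enumeration oracle (recursive leaf count); topology regressions show here.
EXPECTED_PATH_COUNT = 87


def test_first_level_branches_are_the_prophylaxis_adverse_events(trees, bundle):
    for sid in STRATEGIES:
        probs = [p for p, _ in trees[sid].children]
        sp = bundle.strategies[sid]
        assert probs == pytest.approx([sp.p_bleed, sp.p_hit, 1 - sp.p_bleed - sp.p_hit])
    # explicit published first-level values for the no-prophylaxis arm
    assert [p for p, _ in trees["NONE"].children] == pytest.approx([0.020, 0.000, 0.980])


@pytest.mark.parametrize("sid", STRATEGIES)
def test_path_probabilities_conserve_mass(trees, sid):
    total = sum(p for p, *_ in enumerate_paths(trees[sid]))
    assert total == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("sid", STRATEGIES)
def test_terminal_path_count_frozen(trees, sid):
    assert sum(1 for _ in enumerate_paths(trees[sid])) == EXPECTED_PATH_COUNT


@pytest.mark.parametrize("sid", STRATEGIES)
def test_enumeration_agrees_with_recursive_evaluation(trees, outcomes, sid):
    """The two independent evaluation routes must agree to numerical precision."""
    n = outcomes[sid].cohort_size
    p_death = sum(p for p, _, died, _, _ in enumerate_paths(trees[sid]) if died)
    cost = sum(p * c for p, c, *_ in enumerate_paths(trees[sid]))
    assert n * p_death == pytest.approx(outcomes[sid].expected_deaths, rel=1e-9)
    assert n * cost == pytest.approx(outcomes[sid].expected_total_cost, rel=1e-9)


def test_pruning_zero_probability_branches_preserves_expectation(trees):
    full = list(enumerate_paths(trees["NONE"]))
    pruned = list(enumerate_paths(trees["NONE"], prune_zero=True))
    assert len(pruned) < len(full)  # the HIT branch has zero mass without heparin
    for paths in (full, pruned):
        deaths = sum(p for p, _, died, _, _ in paths if died)
        assert deaths == pytest.approx(
            sum(p for p, _, died, _, _ in full if died), rel=1e-12
        )


def test_deaths_by_cause_sum_to_expected_deaths(outcomes):
    for sid in STRATEGIES:
        o = outcomes[sid]
        assert sum(o.deaths_by_cause.values()) == pytest.approx(o.expected_deaths, rel=1e-12)
        assert 0.0 <= o.expected_deaths <= o.cohort_size


def test_total_cost_at_least_the_prophylaxis_course(outcomes, bundle):
    for sid in ("LMWH", "UFH"):
        floor = bundle.population.cohort_size * bundle.strategies[sid].prophylaxis_cost
        assert outcomes[sid].expected_total_cost >= floor


def test_no_modelled_death_when_all_fatality_parameters_are_zero(bundle):
    shared = replace(
        bundle.shared,
        p_death_given_major_bleed=0.0,
        p_death_given_symptomatic_hit=0.0,
        p_death_given_pe_tx_pos=0.0,
        p_death_given_pe_tx_neg=0.0,
        p_sudden_death_given_pe=0.0,
        p_death_given_untreated_pe=0.0,
        p_death_underlying=0.0,
    )
    for sid in STRATEGIES:
        tree = build_tree(bundle.strategies[sid], shared, bundle.costs)
        assert evaluate_tree(tree, 10_000).expected_deaths == 0.0


def test_forced_single_path_tree():
    leaf = TreeNode("fatal", cost=123.0, is_death=True, death_cause="underlying")
    root = TreeNode("root", cost=7.0, children=[(1.0, leaf)])
    out = evaluate_tree(root, 500, "toy")
    assert out.expected_deaths == 500
    assert out.expected_total_cost == pytest.approx(500 * 130.0)


def test_malformed_tree_is_refused():
    a = TreeNode("a", is_death=False, death_cause="none")
    b = TreeNode("b", is_death=True, death_cause="underlying")
    bad = TreeNode("root", children=[(0.5, a), (0.3, b)])
    with pytest.raises(InvalidTreeError):
        evaluate_tree(bad, 100)
    with pytest.raises(InvalidTreeError):
        list(enumerate_paths(bad))
    with pytest.raises(InvalidTreeError):
        TreeNode("leaf-without-payoff")


def test_invalid_bundle_refuses_tree_construction(bundle):
    broken = replace(
        bundle,
        strategies={**bundle.strategies, "LMWH": replace(bundle.strategies["LMWH"], p_dvt=1.5)},
    )
    with pytest.raises(InvalidTreeError):
        build_all_trees(broken)


@pytest.mark.parametrize(
    "parameter",
    ["p_pe_given_untreated_dvt", "p_death_given_untreated_pe", "p_death_underlying"],
)
def test_expected_deaths_monotone_in_lethality_parameters(bundle, parameter):
    grid = [0.0, 0.1, 0.3, 0.6, 1.0]
    for sid in STRATEGIES:
        deaths = []
        for x in grid:
            shared = replace(bundle.shared, **{parameter: x})
            tree = build_tree(bundle.strategies[sid], shared, bundle.costs)
            deaths.append(evaluate_tree(tree, 10_000).expected_deaths)
        assert all(b >= a - 1e-9 for a, b in zip(deaths, deaths[1:]))


def test_strategy_neutrality_limit(bundle):
    """LMWH given the no-prophylaxis risk profile and zero drug cost must
    reproduce the no-prophylaxis outcome exactly."""
    none_sp = bundle.strategies["NONE"]
    neutral = replace(
        bundle.strategies["LMWH"],
        p_dvt=none_sp.p_dvt,
        p_bleed=none_sp.p_bleed,
        p_hit=none_sp.p_hit,
        prophylaxis_cost=0.0,
    )
    a = evaluate_tree(build_tree(neutral, bundle.shared, bundle.costs), 10_000)
    b = evaluate_tree(build_tree(none_sp, bundle.shared, bundle.costs), 10_000)
    assert a.expected_deaths == pytest.approx(b.expected_deaths, rel=1e-12)
    assert a.expected_total_cost == pytest.approx(b.expected_total_cost, rel=1e-12)
    assert a.deaths_by_cause == pytest.approx(b.deaths_by_cause, rel=1e-12)


prob = st.floats(0.0, 1.0, allow_nan=False)
small_prob = st.floats(0.0, 0.5, allow_nan=False)


@given(
    p_dvt=prob,
    p_bleed=small_prob,
    p_hit=small_prob,
    p_sudden=prob,
    p_untx_pe=prob,
    p_under=prob,
)
def test_conservation_under_random_valid_bundles(p_dvt, p_bleed, p_hit, p_sudden, p_untx_pe, p_under):
    """Leaf-path probabilities sum to one for any valid parameter perturbation."""
    base = load_parameters()
    shared = replace(
        base.shared,
        p_sudden_death_given_pe=p_sudden,
        p_death_given_untreated_pe=p_untx_pe,
        p_death_underlying=p_under,
    )
    sp = replace(base.strategies["LMWH"], p_dvt=p_dvt, p_bleed=p_bleed, p_hit=p_hit)
    tree = build_tree(sp, shared, base.costs)
    total = sum(p for p, *_ in enumerate_paths(tree))
    assert math.isclose(total, 1.0, abs_tol=1e-9)
    out = evaluate_tree(tree, 1000)
    assert 0.0 <= out.expected_deaths <= 1000.0


def test_exports_are_renderable(trees):
    outline = tree_outline(trees["LMWH"])
    assert "admission:LMWH" in outline and "DEATH[" in outline
    d = tree_to_dict(trees["UFH"])
    assert d["label"] == "admission:UFH"
    assert sum(c["probability"] for c in d["children"]) == pytest.approx(1.0)
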