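"""One-way scans, threshold bisection, PSA sampling and acceptability curves."""

import numpy as np
import pandas as pd
import pytest

from vte_cea.parameters import CostTable
from vte_cea.sensitivity import (
    build_ceac,
    default_spread_config,
    find_threshold,
    get_parameter,
    one_way_scan,
    run_psa,
    sample_psa_bundle,
    set_parameter,
)

PPEU = "shared.p_pe_given_untreated_dvt"


def zero_spread(bundle):
    return {name: {"fixed": True} for name in default_spread_config(bundle)}


# ---------------------------------------------------------------------------
# parameter addressing

def test_get_and_set_parameter_roundtrip(bundle):
    assert get_parameter(bundle, PPEU) == pytest.approx(0.511)
    assert get_parameter(bundle, "LMWH.p_dvt") == pytest.approx(0.055)
    assert get_parameter(bundle, "costs.treated_dvt") == pytest.approx(10_758)
    new = set_parameter(bundle, PPEU, 0.3)
    assert get_parameter(new, PPEU) == pytest.approx(0.3)
    assert get_parameter(bundle, PPEU) == pytest.approx(0.511)  # original untouched


def test_unknown_parameter_refused(bundle):
    with pytest.raises(KeyError):
        set_parameter(bundle, "shared.not_a_parameter", 0.5)
    with pytest.raises(KeyError):
        one_way_scan("bogus.name", [0.1, 0.2], bundle)
    with pytest.raises(ValueError):
        set_parameter(bundle, "LMWH.p_dvt", 1.5)  # invalid grid value


# ---------------------------------------------------------------------------
# one-way scans

def test_single_point_scan_reproduces_base_case_exactly(bundle, outcomes):
    base_value = get_parameter(bundle, PPEU)
    scan = one_way_scan(PPEU, [base_value], bundle)
    for sid, outs in scan.outcomes.items():
        assert outs[0].expected_deaths == pytest.approx(outcomes[sid].expected_deaths, rel=1e-12)
        assert outs[0].expected_total_cost == pytest.approx(
            outcomes[sid].expected_total_cost, rel=1e-12
        )


def test_deaths_averted_monotone_in_pe_risk_after_untreated_dvt(bundle):
    scan = one_way_scan(PPEU, np.linspace(0.0, 0.511, 9), bundle)
    for sid in ("LMWH", "UFH"):
        averted = [r.deaths_averted for r in scan.cea[sid]]
        assert all(b >= a - 1e-9 for a, b in zip(averted, averted[1:]))


def test_untreated_pe_fatality_scan_spans_published_reduction_ranges(bundle):
    """Across the untreated-PE case-fatality range 0-0.26 the death-rate
    reduction runs ~0.1%->0.5% (LMWH) and ~0%->0.3% (UFH)."""
    scan = one_way_scan("shared.p_death_given_untreated_pe", [1e-9, 0.26], bundle)
    lmwh = [100 * r.death_rate_reduction for r in scan.cea["LMWH"]]
    ufh = [100 * r.death_rate_reduction for r in scan.cea["UFH"]]
    assert round(lmwh[0], 1) == pytest.approx(0.1)
    assert round(lmwh[1], 1) == pytest.approx(0.5)
    assert round(ufh[0], 1) == pytest.approx(0.0)
    assert round(ufh[1], 1) == pytest.approx(0.3)


def test_scan_requires_increasing_grid(bundle):
    with pytest.raises(ValueError):
        one_way_scan(PPEU, [0.3, 0.2], bundle)


# ---------------------------------------------------------------------------
# threshold finding

def test_threshold_matches_dense_grid_oracle(bundle):
    """Bisection must land within one grid step of a dense-scan oracle."""
    tol = 1e-4
    result = find_threshold(PPEU, "both_dominant", (1e-6, 0.511), bundle, tol=tol)
    assert result.status == "found"

    grid = np.linspace(1e-6, 0.511, 2001)
    scan = one_way_scan(PPEU, grid, bundle)
    ok = [
        all(
            scan.cea[s][i].incremental_cost <= 0 and scan.cea[s][i].deaths_averted >= 0
            for s in ("LMWH", "UFH")
        )
        for i in range(len(grid))
    ]
    first_true = grid[ok.index(True)]
    assert result.value == pytest.approx(first_true, abs=(grid[1] - grid[0]) + tol)


def test_threshold_none_in_range_when_always_satisfied(bundle):
    # both strategies save money over the whole upper range
    result = find_threshold(PPEU, "both_cost_saving", (0.3, 0.511), bundle)
    assert result.value is None
    assert result.status == "always_satisfied"


def test_threshold_unknown_criterion_refused(bundle):
    with pytest.raises(KeyError):
        find_threshold(PPEU, "no_such_criterion", (0.0, 0.5), bundle)


# ---------------------------------------------------------------------------
# PSA sampling

def test_zero_spread_sampling_returns_base_bundle(bundle):
    sampled = sample_psa_bundle(bundle, zero_spread(bundle), rng=123)
    assert sampled == bundle


def test_structural_zero_never_sampled(bundle):
    config = default_spread_config(bundle)
    rng = np.random.default_rng(7)
    draws = [sample_psa_bundle(bundle, config, rng).strategies["NONE"].p_hit for _ in range(200)]
    assert set(draws) == {0.0}


def test_sampled_bundles_are_admissible(bundle):
    rng = np.random.default_rng(11)
    for _ in range(50):
        s = sample_psa_bundle(bundle, None, rng)
        for sp in s.strategies.values():
            assert 0.0 <= sp.p_dvt <= 1.0
            assert sp.p_bleed + sp.p_hit <= 1.0
        for f in ("major_bleed", "treated_pe", "dvt_diagnosis"):
            assert getattr(s.costs, f) >= 0.0


def test_sample_means_match_base_values(bundle):
    """Law of large numbers: every sampled parameter's mean over 10,000
    draws lies within 3 standard errors of its base value."""
    n = 10_000
    rng = np.random.default_rng(42)
    config = default_spread_config(bundle)
    names = [
        "LMWH.p_dvt", "UFH.p_bleed", "NONE.p_dvt",
        "shared.p_pe_given_untreated_dvt", "shared.p_death_given_untreated_pe",
        "shared.pe_clin_sens",
        "costs.treated_dvt", "costs.treated_pe", "costs.major_bleed",
    ]
    draws = {name: np.empty(n) for name in names}
    for i in range(n):
        s = sample_psa_bundle(bundle, config, rng)
        for name in names:
            draws[name][i] = get_parameter(s, name)
    for name in names:
        base = get_parameter(bundle, name)
        x = draws[name]
        se = x.std(ddof=1) / np.sqrt(n)
        assert abs(x.mean() - base) < 3 * se, f"{name}: mean {x.mean()} vs base {base}"


def test_missing_spread_entry_refused(bundle):
    config = default_spread_config(bundle)
    config.pop("LMWH.p_dvt")
    with pytest.raises(KeyError):
        sample_psa_bundle(bundle, config, rng=1)


# ---------------------------------------------------------------------------
# run_psa / CEAC

def test_psa_is_reproducible_from_the_seed(bundle):
    a = run_psa(bundle, None, n_iter=40, seed=99)
    b = run_psa(bundle, None, n_iter=40, seed=99)
    pd.testing.assert_frame_equal(a.to_long_frame(), b.to_long_frame())
    pd.testing.assert_frame_equal(a.summary, b.summary)
    c = run_psa(bundle, None, n_iter=40, seed=100)
    assert not a.to_long_frame().equals(c.to_long_frame())


def test_single_zero_spread_iteration_equals_base_case(bundle, outcomes):
    res = run_psa(bundle, zero_spread(bundle), n_iter=1, seed=5)
    for sid, o in res.samples[0].outcomes.items():
        assert o.expected_deaths == pytest.approx(outcomes[sid].expected_deaths, rel=1e-12)
        assert o.expected_total_cost == pytest.approx(outcomes[sid].expected_total_cost, rel=1e-12)


def test_percentile_summary_is_ordered(bundle):
    res = run_psa(bundle, None, n_iter=300, seed=3)
    wide = res.summary.pivot(index="strategy", columns="quantile", values="total_cost")
    assert (wide["low_2.5"] <= wide["median"]).all()
    assert (wide["median"] <= wide["high_97.5"]).all()


def test_ceac_fractions_partition_the_iterations(bundle):
    res = run_psa(bundle, None, n_iter=300, seed=17)
    curve = build_ceac(res.samples, np.linspace(0, 100_000, 9))
    total = sum(np.asarray(p) for p in curve.probabilities.values())
    assert total == pytest.approx(np.ones(9))


def test_zero_spread_ceac_is_a_base_case_step_function(bundle, cea_results):
    """With degenerate distributions the winner at each WTP is decided by
    the base-case net monetary benefit (LMWH dominates at every WTP)."""
    res = run_psa(bundle, zero_spread(bundle), n_iter=5, seed=1)
    wtp = np.linspace(0, 100_000, 5)
    curve = build_ceac(res.samples, wtp)
    for k, lam in enumerate(wtp):
        nmb = {
            sid: lam * cea_results[sid].deaths_averted - cea_results[sid].incremental_cost
            for sid in ("LMWH", "UFH")
        }
        nmb["NONE"] = 0.0
        winner = max(nmb, key=nmb.get)
        assert curve.probabilities[winner][k] == 1.0


def test_ceac_refuses_empty_samples_and_bad_grid(bundle):
    res = run_psa(bundle, zero_spread(bundle), n_iter=1, seed=0)
    with pytest.raises(ValueError):
        build_ceac([], [0, 1000])
    with pytest.raises(ValueError):
        build_ceac(res.samples, [1000, 500])
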