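import pytest
from hypothesis import settings

from vte_cea.cea import compare
from vte_cea.parameters import load_parameters
from vte_cea.tree import build_all_trees, evaluate_tree

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

STRATEGY_ORDER = ("NONE", "LMWH", "UFH")


@pytest.fixture(scope="session")
def bundle():
    return load_parameters()


@pytest.fixture(scope="session")
def trees(bundle):
    return build_all_trees(bundle)


@pytest.fixture(scope="session")
def outcomes(bundle, trees):
    n = bundle.population.cohort_size
    return {sid: evaluate_tree(tree, n, sid) for sid, tree in trees.items()}


@pytest.fixture(scope="session")
def cea_results(outcomes):
    return {sid: compare(outcomes[sid], outcomes["NONE"]) for sid in ("LMWH", "UFH")}
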