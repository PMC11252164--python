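import pytest

from gqcycle import WT, fold_changes, load_preset, parse_genotype, solve_steady_state

GENOTYPES = (
    "GNAQ:Q209L:het",
    "GNAQ:Q209L:hom",
    "GNAQ:Q209P:het",
    "GNAQ:Q209P:hom",
    "GNAQ:R183C:het",
    "GNAQ:R183C:hom",
    "CYSLTR2:L129Q:het",
)


@pytest.fixture(scope="session")
def initial_params():
    return load_preset("initial")


@pytest.fixture(scope="session")
def revised_params():
    return load_preset("revised")


def _solve_all(params):
    """Steady states and folds for the WT baseline and every shipped genotype."""
    base = solve_steady_state(params, WT)
    results = {"WT": base}
    for g in GENOTYPES:
        r = solve_steady_state(params, parse_genotype(g))
        fold_changes(r, base)
        results[g] = r
    return results


@pytest.fixture(scope="session")
def initial_results(initial_params):
    return _solve_all(initial_params)


@pytest.fixture(scope="session")
def revised_results(revised_params):
    return _solve_all(revised_params)
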