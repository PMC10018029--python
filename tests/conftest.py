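import pytest

import hfcea


@pytest.fixture(scope="session")
def base_inputs():
    """The packaged base-case inputs: (ParameterSet, LifeTable, CpiChain)."""
    return hfcea.base_case_fixture()


@pytest.fixture(scope="session")
def base_params(base_inputs):
    return base_inputs[0]


@pytest.fixture(scope="session")
def life_table(base_inputs):
    return base_inputs[1]


@pytest.fixture(scope="session")
def cpi(base_inputs):
    return base_inputs[2]


@pytest.fixture(scope="session")
def base_runs(base_params, life_table):
    """Base-case RunResults for all three strategies."""
    return {
        name: hfcea.run_strategy(name, base_params, life_table)
        for name in ("enalapril", "sv_early", "sv_late")
    }


@pytest.fixture(scope="session")
def base_psa(base_params, life_table):
    """The full 10,000-draw probabilistic sensitivity analysis (seeded).

    Session-scoped: it is by far the most expensive computation in the suite
    and several checks (acceptability, CEAC, crossing, determinism of the
    headline number) read from the same run.
    """
    return hfcea.run_psa(base_params, life_table, 10_000, seed=0, log_every=0)
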