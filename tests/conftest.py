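import pytest

from farm import fixtures as fx


@pytest.fixture
def input_cycle():
    return fx.input_cycle()


@pytest.fixture
def linear_chain():
    return fx.linear_chain(n=4)


@pytest.fixture
def dual_route():
    return fx.dual_route_sl()


@pytest.fixture
def cheat():
    return fx.transport_cheat()


@pytest.fixture
def all_motifs():
    """One instance of every motif, for sweep-style invariant checks."""
    return [
        fx.input_cycle(),
        fx.linear_chain(n=4),
        fx.branch_rescue(),
        fx.dual_route_sl(),
        fx.dual_route_sl(shared_pathway=False),
        fx.isozyme_sl(),
        fx.transport_cheat(),
        fx.dead_end(k=3),
    ]
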