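import pytest

from clonotrack.synthetic_data import SimConfig, simulate_all


def small_config(seed=3):
    """Desk-scale layout: 20 repertoires, ~50 queries, short repertoires."""
    return SimConfig(
        seed=seed,
        n_hd_bulk=5, n_t1d_bulk=3, n_hd_tregscm=1, n_t1d_tregscm=1,
        clones_per_repertoire=400, reads_per_repertoire=5000,
        n_hd_sc=3, n_t1d_sc=3, clonotypes_per_donor=9,
        n_hd_only=2, n_t1d_only=2, n_expansions=4, n_confined=2,
    )


@pytest.fixture(scope="session")
def default_sim():
    """The full emulated design: 94 repertoires, 12 single-cell donors."""
    return simulate_all(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    return simulate_all(small_config())
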