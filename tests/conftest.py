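import pytest

from associnet.synthetic import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """60-protein fixture with 4 planted pathways and faithful 1:1 orthology."""
    return generate_fixture(FixtureSpec(seed=3))


@pytest.fixture(scope="session")
def tiny_fixture():
    """12-protein fixture small enough for alignment-based remapping."""
    return generate_fixture(
        FixtureSpec(
            n_template_proteins=12,
            n_query_proteins=12,
            n_pathways=1,
            pathway_sizes=(6,),
            background_edge_rate=0.05,
            seed=11,
        )
    )
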