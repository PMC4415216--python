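import pytest

from pathpanel import simulate_knowledge_base


@pytest.fixture(scope="session")
def small_kb():
    """A small synthetic knowledge base shared by fast unit tests."""
    return simulate_knowledge_base(
        n_genes=200,
        n_pathways=50,
        hub_fraction=0.05,
        n_redundant_pairs=2,
        n_coexpression_clusters=2,
        n_high_disease=50,
        seed=11,
    )
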