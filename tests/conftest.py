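import dendropy
import pytest

import hapmet as hm


@pytest.fixture
def toy_alignment() -> hm.SequenceAlignment:
    """Three haplotypes: i1/i2 identical, i3 one step away from them, i4
    three steps from i1/i2 (four from i3)."""
    return hm.SequenceAlignment(
        (
            ("i1", "AAAAAA"),
            ("i2", "AAAAAA"),
            ("i3", "AAAAAT"),
            ("i4", "AATTTA"),
        )
    )


@pytest.fixture
def toy_rooted(toy_alignment) -> hm.RootedNetwork:
    haps = hm.collapse_haplotypes(toy_alignment)
    return hm.root_network(hm.build_network(haps))


@pytest.fixture
def toy_traits() -> hm.TraitTable:
    return hm.TraitTable.from_rates(
        {"i1": 1.0, "i2": 2.0, "i3": 4.0, "i4": 8.0}
    )


@pytest.fixture
def balanced_tree() -> dendropy.Tree:
    return dendropy.Tree.get(
        data="((A:1.0,B:1.0):0.5,(C:1.0,D:1.0):0.5);",
        schema="newick",
        rooting="force-rooted",
    )


@pytest.fixture(scope="session")
def small_dataset() -> hm.SyntheticDataset:
    """A 15-individual study-shaped dataset shared across tests."""
    return hm.generate_study_dataset(
        hm.SimulationConfig(
            n_individuals=15, seq_length=300, n_posterior_trees=12, seed=42
        )
    )
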