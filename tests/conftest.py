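import pytest

from lepcompgen import rearrphylo, synthio
from lepcompgen.io import parse_newick


@pytest.fixture()
def butterfly_tree():
    """The 7-taxon morphology-based reference topology."""
    return parse_newick(rearrphylo.TRADITIONAL_NEWICK)


@pytest.fixture()
def small_diploid():
    return synthio.simulate_diploid(60_000, free_fraction=0.1, seed=42)


def split_scenario_diploid(length=150_000, seed=0):
    """Diploid for haplotig-merge scenarios: high-heterozygosity regions that
    escape assembly merging are a minority of the genome, so the coverage
    mode sits on the diploid peak."""
    return synthio.simulate_diploid(
        length, mix_weights=(0.85, 0.15), free_fraction=0.1, seed=seed
    )


from lepcompgen.experiments import additive_matrix, random_tree_with_lengths  # noqa: E402,F401
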