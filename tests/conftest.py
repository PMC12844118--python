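import pytest

from ectoconv.genome_io import GeneModel, Genome
from ectoconv.simulate import ConversionSpec, SimParams, SplitSpec, simulate_dataset


@pytest.fixture
def toy_genome() -> Genome:
    """Three-gene single-chromosome genome with one minus-strand gene."""
    #          0         1         2         3
    #          0123456789012345678901234567890123456789
    seq = "GGGATGAAATGACCCTCACATGGGATGTGATTTGGGCCCA"
    genes = [
        GeneModel("g1", "chr1", 3, 12, "+", ((3, 12),)),
        GeneModel("g2", "chr1", 15, 21, "-", ((15, 21),)),
        GeneModel("g3", "chr1", 24, 30, "+", ((24, 27), (27, 30))),
    ]
    return Genome({"chr1": seq}, {"chr1": genes})


@pytest.fixture
def small_params() -> SimParams:
    """Compact simulation: 4-gene duplication block, quick to scan."""
    return SimParams(
        seed=11,
        n_genes_region=12,
        n_genes_background=24,
        loss_prob_affected=0.15,
        loss_prob_background=0.02,
        conversion_events=(
            ConversionSpec("A", 0, 1.0, 1),
            ConversionSpec("B", 1, 1.0, 2),
        ),
        split_events=(SplitSpec("B", 3, arm=1, n_daughters=3, mode="point"),),
    )


@pytest.fixture
def small_dataset(small_params):
    return simulate_dataset(small_params)
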