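import numpy as np
import pytest

from spongemag.io import GeneFeature
from spongemag.simulate import (
    CohortSpec,
    GenomeSpec,
    default_planted_effects,
    gen_cohort,
    gen_genome,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Default group sizes, 200 features, 10 planted effects — quick pipeline food."""
    effects = default_planted_effects(n_enriched=5, n_depleted=5, seed=11)
    spec = CohortSpec(n_features=200, planted_effects=effects, seed=11)
    return gen_cohort(spec)


@pytest.fixture(scope="session")
def planted_genome():
    """One genome with a single detector-valid planted cluster."""
    return gen_genome(GenomeSpec(genome_id="gpos", plant_cluster=True, seed=5))


@pytest.fixture
def toy_genes():
    """Canonical adjacent steroid trio on the plus strand with flanks."""
    mk = lambda s, e, strand, fid: GeneFeature(
        "g1", "ctg1", s, e, strand, fid
    )
    return [
        mk(10, 800, "+", "K00001"),
        mk(1000, 1900, "+", "DFR"),
        mk(1950, 2300, "+", "hypothetical"),
        mk(2400, 3800, "+", "ERG24"),
        mk(3900, 5400, "+", "CYP51"),
        mk(5500, 8350, "+", "ERG7"),
        mk(8400, 9300, "-", "SMT1"),
        mk(9500, 10400, "+", "K00161"),
    ]
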