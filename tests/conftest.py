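import numpy as np
import pytest

from virosift import profiles, synthetic


@pytest.fixture(scope="session")
def models_small():
    return synthetic.default_models(reads_per_contig=400)


@pytest.fixture(scope="session")
def small_fixture(models_small):
    """3 classes x 4 contigs, 400 reads each, single pool, fixed seeds."""
    contigs, truth = synthetic.simulate_contigs(
        {"sirna": 4, "pirna": 4, "degradation": 4},
        length_range=(600, 1200),
        seed=11,
    )
    reads, alignments = synthetic.simulate_reads(contigs, truth, models_small, seed=12)
    return contigs, truth, reads, alignments


@pytest.fixture(scope="session")
def small_profiles(small_fixture):
    contigs, truth, reads, alignments = small_fixture
    return profiles.compute_profiles(
        alignments,
        [c.id for c in contigs],
        pool_by_contig={c.id: c.pool_id for c in contigs},
    )


def random_profile(rng, total=500):
    """A random non-degenerate 42-cell profile."""
    weights = rng.random(42)
    counts = rng.multinomial(total, weights / weights.sum())
    return profiles.SizeStrandProfile("random", counts)
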