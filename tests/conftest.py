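import numpy as np
import pytest

from hairsnag.consensus import consensus_dataset, filter_by_locus_coverage
from hairsnag.identify import cluster_samples
from hairsnag.model import LocusGenotype, MultilocusGenotype
from hairsnag.simulate import generate_study_like_dataset


@pytest.fixture(scope="session")
def study():
    """One study-like synthetic dataset, consensus-called, with truth table."""
    dataset, truth = generate_study_like_dataset(seed=1)
    called = consensus_dataset(dataset)
    return dataset, called, truth


@pytest.fixture(scope="session")
def study_individuals(study):
    _, called, truth = study
    retained, _ = filter_by_locus_coverage(called, min_loci=8)
    individuals = cluster_samples(retained, called.repeat_units)
    return individuals, truth


def make_mlg(pairs, loci=None):
    """MultilocusGenotype from a list of (a, b) tuples or None per locus."""
    loci = loci or [f"L{i+1:02d}" for i in range(len(pairs))]
    calls = {}
    for name, pair in zip(loci, pairs):
        if pair is None:
            calls[name] = LocusGenotype()
        else:
            calls[name] = LocusGenotype(*pair)
    return MultilocusGenotype(calls)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
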