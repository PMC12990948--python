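import random

import pytest

from glycanidx import VOCABULARY, normalize_distribution


@pytest.fixture
def rng():
    return random.Random(20260928)


def random_raw_distribution(rnd, species=VOCABULARY, max_species=None):
    """Random positive abundances over a subset of the vocabulary, sum 100."""
    k = rnd.randint(2, max_species or len(species))
    chosen = rnd.sample(list(species), k)
    weights = [rnd.random() + 1e-6 for _ in chosen]
    total = sum(weights)
    return {s: 100.0 * w / total for s, w in zip(chosen, weights)}


@pytest.fixture
def random_distribution(rng):
    return normalize_distribution(random_raw_distribution(rng), tolerance=1e-6)
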