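import numpy as np
import pytest

import multida as mda


@pytest.fixture(scope="session")
def graph():
    return mda.default_genomic_graph()


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced-size draw of the default simulation scheme."""
    return mda.simulate_dataset(mda.SimConfig(n=120), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def random_multiblock():
    """Factory for unstructured random data in the five-block layout."""

    def make(seed, n=40, widths=(6, 8, 10, 5)):
        rng = np.random.default_rng(seed)
        blocks = [rng.standard_normal((n, p)) for p in widths]
        labels = rng.choice([0, 1], size=n)
        while len(np.unique(labels)) < 2:  # pragma: no cover
            labels = rng.choice([0, 1], size=n)
        return mda.prepare(blocks, labels)

    return make
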