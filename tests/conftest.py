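import numpy as np
import pytest

from pinescape.core import GenotypeMatrix
from pinescape.synthdata import SynthConfig, gen_im_dataset


def small_config(seed: int = 3, n_loci: int = 600, n_adaptive: int = 0,
                 **kw) -> SynthConfig:
    """A 12-population, 3-cluster configuration small enough for unit tests."""
    sizes = {f"P{i}": 6 for i in range(12)}
    clusters = {f"P{i}": ("north" if i < 6 else "west" if i < 10 else "south")
                for i in range(12)}
    coords = {
        f"P{i}": (100 + 2 * i + 0.3 * (i % 3),
                  30 + (8 if i < 6 else 2 if i < 10 else -4) + 0.7 * (i % 2))
        for i in range(12)
    }
    kw.setdefault("missing_rate", 0.05)
    return SynthConfig(pop_sizes=sizes, cluster_assignment=clusters,
                       coords=coords, n_loci=n_loci, n_adaptive=n_adaptive,
                       seed=seed, **kw)


@pytest.fixture(scope="session")
def small_bundle():
    return gen_im_dataset(small_config())


@pytest.fixture(scope="session")
def spiked_bundle():
    return gen_im_dataset(small_config(seed=11, n_loci=800, n_adaptive=20,
                                       adaptive_beta=3.0))


@pytest.fixture()
def toy_matrix():
    """Tiny deterministic genotype matrix with missingness (2 pops x 4+4)."""
    rng = np.random.default_rng(12345)
    calls = rng.integers(0, 3, size=(8, 6)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.15] = -1
    G = GenotypeMatrix(calls, [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
                       [f"L{j}" for j in range(6)])
    popmap = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
    return G, popmap
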