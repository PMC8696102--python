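import numpy as np
import pytest

from mstalign import FamilySpec, Params, make_chain, make_family
from mstalign.evolve import PairPool

# two-domain template used throughout: three helix/strand/loop repeats,
# 60 residues, packed in two layers
ARCH = (
    ("helix", 10), ("strand", 6), ("loop", 4),
    ("helix", 10), ("loop", 4), ("strand", 6),
    ("helix", 10), ("loop", 4), ("strand", 6),
)


@pytest.fixture(scope="session")
def template():
    return make_chain(ARCH, seed=0)


@pytest.fixture(scope="session")
def noisy_pair():
    """Two noisy copies of the template (sigma = 0.3 Å)."""
    structures, truth = make_family(FamilySpec(architecture=ARCH, n_copies=2, noise_sigma=0.3, seed=1))
    return structures, truth


@pytest.fixture(scope="session")
def family3():
    """Three noisy copies with ground truth."""
    structures, truth = make_family(FamilySpec(architecture=ARCH, n_copies=3, noise_sigma=0.2, seed=11))
    return structures, truth


@pytest.fixture(scope="session")
def family3_pool(family3):
    structures, _ = family3
    return PairPool(structures, Params())


@pytest.fixture(scope="session")
def permuted_pair():
    """Template plus its circular permutant (cut at 30), sigma = 0.2 Å."""
    spec = FamilySpec(architecture=ARCH, n_copies=2, noise_sigma=0.2, permuted_copies={1: 30}, seed=5)
    return make_family(spec)


@pytest.fixture(scope="session")
def hinged_pair():
    """Template plus a copy with the second domain rotated 60° (no noise)."""
    spec = FamilySpec(architecture=ARCH, n_copies=2, noise_sigma=0.0, hinges={1: (30, 60.0)}, seed=3)
    return make_family(spec)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
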