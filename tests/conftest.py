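import numpy as np
import pytest

from triadgeo.fixtures import (
    EnsembleSpec,
    FixtureSpec,
    make_holo_from_apo,
    make_toy_hydrolase,
)
from triadgeo.structure_io import ResidueSpec

LOOP_SHIFT_ATOMS = [
    (ResidueSpec("GLY", s), a) for s in (9, 10, 11, 12) for a in ("N", "CA", "C", "O")
]
SHIFT_DIRECTION = np.array([0.0, -0.6, 0.8])  # unit vector, off-axis


@pytest.fixture(scope="session")
def toy():
    """Clean 4-chain toy hydrolase + site definition."""
    model, site = make_toy_hydrolase(FixtureSpec(seed=7))
    return model, site


@pytest.fixture(scope="session")
def toy_pair():
    """Apo/holo pair with a planted 0.75 Å loop shift and no noise."""
    apo, site = make_toy_hydrolase(FixtureSpec(seed=11))
    spec = FixtureSpec(
        seed=11, planted_loop_shift=(LOOP_SHIFT_ATOMS, 0.75 * SHIFT_DIRECTION)
    )
    holo, truth = make_holo_from_apo(apo, spec)
    return apo, holo, site, truth


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish proper rotation from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
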