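import os

# single-threaded BLAS: avoids oversubscription thrash on small matmuls
for var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(var, "1")

import numpy as np
import pytest

from tomoshot.phantoms import apply_pose, phantom_library, random_pose
from tomoshot.simulate import SubtomogramRecord, TomoDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_posed_dataset(n_classes=6, per_class=6, n_test_classes=2, seed=0,
                       noise_std=0.0):
    """Fast in-memory dataset of randomly posed phantom records (no
    tilt-series simulation) for unit tests of episodes/training/CRF."""
    maps = phantom_library()[:n_classes]
    rng = np.random.default_rng(seed)
    records = []
    names = [m.name for m in maps]
    test_classes = names[-n_test_classes:]
    train_classes = names[:-n_test_classes]
    for m in maps:
        for _ in range(per_class):
            pose = random_pose(rng, max_translation=0.5)
            vol = apply_pose(m.grid, pose)
            mask = vol > 0
            if noise_std:
                vol = vol + rng.normal(0, noise_std, vol.shape).astype(np.float32)
            records.append(SubtomogramRecord(
                vol, m.name, mask, pose, np.inf,
                split="test" if m.name in test_classes else "train"))
    return TomoDataset(records, names, train_classes, test_classes, np.inf, seed)


@pytest.fixture(scope="session")
def posed_dataset():
    return make_posed_dataset()
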