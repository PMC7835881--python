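"""Reference desk-scale benchmark: a small, fully seeded end-to-end
experiment (6 geometric phantom classes, 4 train / 2 test, SNR infinity)
sized to run on a single CPU in minutes.

The full-scale protocol (600x600x300 tomograms, 10,000 particles, 22
classes) is available through SimulationConfig/TrainConfig but is far too
large for routine runs; this module pins the problem sizes used by the
package's own regression checks and by scripts/acceptance.py.
"""

from __future__ import annotations

import numpy as np

from .crf import CRFParams
from .model import ModelConfig
from .phantoms import phantom_library
from .simulate import SimulationConfig, TomoDataset, build_dataset
from .training import TrainConfig, TrainResult, evaluate_nway, train

__all__ = ["benchmark_dataset", "benchmark_model_config",
           "benchmark_train_config", "benchmark_run", "benchmark_crf_params"]

N_CLASSES = 6
N_TEST_CLASSES = 2


TEST_CLASSES = ("torus", "lshape")  # fixed hold-out pair, as in a fixed
                                    # full-scale class split; the seed drives
                                    # poses, packing and training only


def benchmark_dataset(seed: int) -> TomoDataset:
    """6-class phantom dataset: 150^3-ish tomogram, ~150 particles, SNR inf."""
    config = SimulationConfig(
        tomogram_shape=(150, 150, 100), n_particles=150, snr=np.inf,
        test_classes=TEST_CLASSES, seed=seed,
    )
    return build_dataset(config, phantom_library()[:N_CLASSES])


def benchmark_model_config(seed: int, decoder: bool = True,
                           duse: bool = True) -> ModelConfig:
    # wide deepest level: with n_pools=2 its convolutions run at 8^3, so the
    # extra latent capacity costs almost nothing
    return ModelConfig(channels=(4, 8, 32), n_pools=2, seed=seed,
                       decoder_enabled=decoder, duse_enabled=duse,
                       decoder_skips=decoder)


def benchmark_train_config(seed: int, epochs: int = 24) -> TrainConfig:
    return TrainConfig(n_way=2, episodes_per_epoch=8, epochs=epochs,
                       learning_rate=1e-3, decoder_lr_scale=5.0, seed=seed)


def benchmark_crf_params() -> CRFParams:
    return CRFParams()


def benchmark_run(dataset: TomoDataset, seed: int, decoder: bool = True,
                  epochs: int = 24) -> TrainResult:
    """Train one benchmark model (decoder on or off) on the dataset."""
    return train(dataset, benchmark_model_config(seed, decoder=decoder),
                 benchmark_train_config(seed + 1000, epochs=epochs))


def benchmark_evaluate(model, dataset: TomoDataset, seed: int,
                       n_way: int = 2, episodes: int = 500,
                       with_dsc: bool = False):
    rng = np.random.default_rng(seed)
    return evaluate_nway(
        model, dataset, n_way, episodes, rng,
        crf_params=benchmark_crf_params() if with_dsc else None,
        max_dsc_records_per_class=8 if with_dsc else 0,
        rotation_average=True,
    )
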