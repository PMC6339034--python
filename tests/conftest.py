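import numpy as np
import pytest

from riemgait.config import PipelineConfig
from riemgait.synthetic import (
    GaitSimConfig,
    generate_dataset,
    sample_subjects,
    simulate_sequence,
    toy_skeleton,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def skeleton():
    return toy_skeleton()


def random_unit_vectors(rng, n):
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@pytest.fixture(scope="session")
def walker_40():
    """Noiseless synthetic walker: period 40 frames, 200 frames total."""
    cfg = GaitSimConfig(n_subjects=1, cycles_per_subject=1, frames_per_cycle=40,
                        cycles_per_sequence=5, within_subject_noise=0.0, seed=5)
    style = sample_subjects(cfg)[0]
    seq = simulate_sequence(style, 5, cfg, sequence_id="walker40")
    return seq, cfg


@pytest.fixture(scope="session")
def small_dataset():
    """4 subjects x 6 sequences, strong subject signal, toy skeleton."""
    cfg = PipelineConfig()
    cfg.simulate = GaitSimConfig(
        n_subjects=4, cycles_per_subject=6, frames_per_cycle=24,
        cycles_per_sequence=3, seed=3)
    cfg.preprocess.target_frames = 24
    sequences, skel = generate_dataset(cfg.simulate)
    return sequences, skel, cfg
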