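import numpy as np
import pytest

import noise2average as n2a


@pytest.fixture(scope="session")
def structural_phantom():
    return n2a.make_structural_phantom((64, 64, 64), seed=7)


@pytest.fixture(scope="session")
def noisy_pair(structural_phantom):
    """Two repetitions at sigma = 0.3, no misalignment (idealized noise law)."""
    sim = n2a.SimulationConfig(sigma=0.3, n_repetitions=2, misalign=False, seed=11)
    return n2a.simulate_repetitions(structural_phantom, sim)


@pytest.fixture(scope="session")
def tensor_phantom():
    return n2a.make_tensor_phantom((48, 48, 48), seed=3)


@pytest.fixture(scope="session")
def seven_channel_scheme():
    """1 b=0 plus 6 well-conditioned directions (full-rank design)."""
    scheme, _ = n2a.optimize_directions(restarts=10, seed=0, polish_top=3, polish_rounds=2)
    dirs = np.vstack([[0.0, 0.0, 1.0], scheme.directions])
    bvals = np.concatenate([[0.0], np.full(6, 1000.0)])
    return n2a.DirectionSet(dirs, bvals)


@pytest.fixture(scope="session")
def pretrained_tiny_model():
    """A small denoiser pretrained on a synthetic structural corpus.

    Mirrors the transfer-learning workflow: supervised pretraining on
    simulated noisy/clean pairs from several phantom "subjects", later
    fine-tuned on the data being denoised.
    """
    corpus = [n2a.make_structural_phantom((48, 48, 48), seed=100 + i) for i in range(4)]
    sim = n2a.SimulationConfig(sigma=0.5, n_repetitions=2, misalign=False, seed=200)
    ncfg = n2a.NetworkConfig(depth=4, channels=8, input_channels=1, output_channels=1)
    tcfg = n2a.TrainingConfig(loss="mse", epochs=25, seed=9,
                              lr_phases=[(1e-3, 25), (1e-4, 10)])
    return n2a.pretrain_on_corpus(corpus, sim, ncfg, tcfg,
                                  block_shape=(24, 24, 24), seed=9)
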