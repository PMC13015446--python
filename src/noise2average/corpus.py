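"""Default pretraining-corpus noise conditions.

Pretraining simulates noisy/clean pairs from high-SNR volumes.  For
T1w-style corpora the noise level is 0.5 times the brain-voxel intensity
standard deviation; for diffusion corpora, 0.1 for b = 0 channels and 0.3
for diffusion-weighted channels.
"""

from __future__ import annotations

import numpy as np

from .dti import DirectionSet
from .synthetic import SimulationConfig

__all__ = [
    "T1W_SIGMA",
    "DIFFUSION_B0_SIGMA",
    "DIFFUSION_DWI_SIGMA",
    "t1w_corpus_config",
    "diffusion_corpus_sigma",
    "diffusion_corpus_config",
]

T1W_SIGMA = 0.5
DIFFUSION_B0_SIGMA = 0.1
DIFFUSION_DWI_SIGMA = 0.3


def t1w_corpus_config(n_repetitions: int = 2, seed: int = 0) -> SimulationConfig:
    """Corpus simulation settings for structural (T1w-style) pretraining."""
    return SimulationConfig(sigma=T1W_SIGMA, n_repetitions=n_repetitions,
                            misalign=False, seed=seed)


def diffusion_corpus_sigma(scheme: DirectionSet) -> np.ndarray:
    """Per-channel relative noise level for a diffusion corpus."""
    return np.where(scheme.bvalues == 0, DIFFUSION_B0_SIGMA, DIFFUSION_DWI_SIGMA)


def diffusion_corpus_config(scheme: DirectionSet, n_repetitions: int = 2,
                            seed: int = 0) -> SimulationConfig:
    """Corpus simulation settings for diffusion pretraining (per-channel sigma)."""
    return SimulationConfig(sigma=diffusion_corpus_sigma(scheme),
                            n_repetitions=n_repetitions, misalign=False, seed=seed)
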