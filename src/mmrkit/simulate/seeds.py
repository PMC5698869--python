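"""Deterministic child-seed derivation.

All generators take a single root seed; per-subject / per-block streams are
spawned through :class:`numpy.random.SeedSequence` with a documented spawn
key, so any subset of the simulated study can be regenerated independently
of the rest.
"""

from __future__ import annotations

import numpy as np

# fixed stream ids per generator family
STREAM_STIMULI = 1
STREAM_GENOTYPES = 2
STREAM_PHENOTYPES = 3
STREAM_EEG = 4


def child_seed(root_seed: int, *key: int) -> np.random.SeedSequence:
    """SeedSequence for stream ``key`` (e.g. ``(STREAM_EEG, subject, block)``)."""
    return np.random.SeedSequence(entropy=int(root_seed), spawn_key=tuple(int(k) for k in key))


def rng_for(root_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(root_seed, *key))
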