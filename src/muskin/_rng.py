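"""Seed plumbing: every randomized operation takes an explicit seed (int
or SeedSequence); no global random state anywhere in the package."""

from __future__ import annotations

import numpy as np


def seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
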