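"""Deterministic random-stream derivation.

One integer seed governs a whole run; per-stage sub-streams are derived
through `numpy.random.SeedSequence` with fixed integer keys so that adding
a stage never perturbs the draws of another.
"""

from __future__ import annotations

import numpy as np


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Return a Generator for the sub-stream identified by ``keys``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


def derived_seed(seed: int, *keys: int) -> int:
    """A plain integer seed (< 2**31) derived from ``seed`` and ``keys``.

    Needed where third-party estimators accept only an integer
    ``random_state``.
    """
    state = np.random.SeedSequence([int(seed), *map(int, keys)]).generate_state(1)[0]
    return int(state % (2**31))
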