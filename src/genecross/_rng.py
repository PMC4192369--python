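"""Seed-substream derivation.

Every random draw in the package flows from one global integer seed.
Per-stage generators are derived by keying a ``SeedSequence`` with a
stable hash of the stage name, so any stage can be re-run in isolation
and reproduce exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _name_key(name: str) -> int:
    # crc32 is stable across platforms and python versions (unlike hash()).
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, stage: str) -> np.random.Generator:
    """Return the named random-generator substream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _name_key(stage)]))


def spawn_seed(seed: int, stage: str) -> int:
    """A derived integer seed (< 2**31) for the named stage."""
    return int(np.random.SeedSequence([int(seed), _name_key(stage)]).generate_state(1)[0] % (2**31))
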