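"""Named per-stage random streams derived from one master seed.

Each pipeline stage draws from an independent stream obtained by spawning
the master ``SeedSequence`` with a spawn key derived from the stage name
(CRC-32 of the UTF-8 name).  Stages are therefore reproducible in
isolation: re-running one stage with the same master seed gives the same
stream regardless of what ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed_sequence(master_seed: int, stage: str) -> np.random.SeedSequence:
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(key,))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage under a master seed."""
    return np.random.default_rng(stage_seed_sequence(master_seed, stage))
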