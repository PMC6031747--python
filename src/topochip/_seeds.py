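"""Stage-scoped seed derivation.

One master seed drives every stochastic stage.  Per-stage generators are
derived by hashing the stage name, so adding or reordering stages never
shifts another stage's random stream.
"""

import zlib

import numpy as np


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    # crc32 is stable across platforms and Python versions
    return np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode("utf-8"))])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))
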