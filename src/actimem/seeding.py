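"""Reproducible per-stage random streams.

A single master seed drives the whole pipeline.  Each stage draws from an
independent child stream derived as ``SeedSequence([master, crc32(stage)])``
so any stage can be re-run in isolation and still produce the numbers the
full pipeline would.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed_sequence(master_seed: int, stage: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode("utf-8"))])


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed_sequence(master_seed, stage))


def stage_int_seed(master_seed: int, stage: str) -> int:
    """A plain integer seed (< 2**31) for libraries that take one."""
    return int(stage_seed_sequence(master_seed, stage).generate_state(1)[0] % (2**31 - 1))
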