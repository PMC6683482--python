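"""Seed-substream derivation.

Every stochastic stage of a study (pedigree generation, EPD sampling, panel
draws, each replicate's gene drop, genotyping scheme and optimizer run) gets
its own named substream derived from a single master seed, so that re-running
any stage in isolation reproduces it exactly.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream_seed(master_seed: int, *names: object) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed and names."""
    tag = ":".join([str(int(master_seed))] + [str(n) for n in names])
    digest = hashlib.sha256(tag.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(master_seed: int, *names: object) -> np.random.Generator:
    """A numpy Generator on the named substream of ``master_seed``."""
    return np.random.default_rng(substream_seed(master_seed, *names))
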