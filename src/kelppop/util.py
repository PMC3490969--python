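"""Seed plumbing: every stage draws from a named substream of one master
seed so permutation and bootstrap P-values are reproducible per stage."""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
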