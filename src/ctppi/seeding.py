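"""Deterministic seed derivation.

Every stochastic stage derives its own 31-bit seed from the master seed and a
stable textual token (stage name, term id, replicate index), so per-module
results do not depend on catalog ordering.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, stage: str, token: str = "") -> int:
    if master < 0:
        raise ValueError("master seed must be non-negative")
    h = zlib.crc32(f"{stage}:{token}".encode("utf-8"))
    ss = np.random.SeedSequence([int(master), h])
    return int(ss.generate_state(1)[0] % (2**31))
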