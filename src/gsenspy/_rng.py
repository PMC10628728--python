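"""Deterministic seed substreams.

One master seed drives the whole pipeline; each stage gets its own
independent Generator derived from (master seed, stage label) so that
adding or re-ordering stages never perturbs the draws of another stage.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for stage `label` derived from `seed`.

    The label is hashed with CRC-32 (stable across platforms and Python
    processes, unlike the builtin hash) and mixed into a SeedSequence.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
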