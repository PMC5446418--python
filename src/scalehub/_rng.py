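"""Deterministic seed derivation.

All randomness in the package flows from one master seed; sub-seeds for
(subject, scale, repeat, ...) are derived by feeding the master seed and the
integer key path into numpy's SeedSequence (a counter-based mixing function),
then reducing to a 31-bit integer so derived seeds remain portable.
"""

from __future__ import annotations

import numpy as np


def derive_seed(master_seed: int, *keys: int) -> int:
    """Mix ``master_seed`` with an integer key path into a sub-seed < 2**31."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
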