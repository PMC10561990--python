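"""Deterministic seed derivation.

Every fitted model in the stack gets its own seed derived from the global
seed and its coordinates in the model grid, so serial and parallel runs fit
bit-identical models regardless of scheduling order.
"""

from __future__ import annotations

import numpy as np

# Namespaces keep base-model cells, meta fits and data simulation from ever
# colliding in seed space.
NS_BASE = 0
NS_META = 1
NS_SIM = 2
NS_BENCH = 3


def derive_seed(global_seed: int, *coords: int) -> int:
    """Derive a child seed from a global seed and integer coordinates.

    Pure function of its arguments; the result fits in a signed 32-bit int so
    it is accepted as ``random_state`` everywhere.
    """
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=tuple(int(c) for c in coords))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
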