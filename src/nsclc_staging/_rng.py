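"""Named, reproducible random streams.

A single master seed spawns independent substreams for each named
sub-component (cohort generation, embedding init, dropout, sampling, ...),
so any component can be re-run in isolation with the identical stream.
"""

from __future__ import annotations

import numpy as np

__all__ = ["stream", "spawn_seed"]

_MOD = 2**31 - 1


def spawn_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit child seed from (master_seed, name)."""
    ss = np.random.SeedSequence([int(master_seed) % _MOD, _name_key(name)])
    return int(ss.generate_state(1)[0]) % _MOD


def stream(master_seed: int, name: str) -> np.random.Generator:
    """Independent Generator for the named sub-component."""
    return np.random.default_rng(spawn_seed(master_seed, name))


def _name_key(name: str) -> int:
    # stable across processes (no PYTHONHASHSEED dependence)
    key = 0
    for ch in name:
        key = (key * 131 + ord(ch)) % _MOD
    return key
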