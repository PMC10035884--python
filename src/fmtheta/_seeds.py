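"""Counter-based seed derivation.

Every stochastic routine in the package takes an explicit integer seed and
derives independent substreams with :func:`child_seed` /
:func:`child_rng`, so that regenerating one subject, session or block
never perturbs any other stream (reproducibility under reordering).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError(f"seed keys must be non-negative, got {key}")
        return int(key)
    return zlib.crc32(str(key).encode("utf-8"))


def child_seed(master_seed: int, *keys: int | str) -> int:
    """Derive a deterministic child seed below 2**31 from a master seed
    and an arbitrary tuple of integer/string keys."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=tuple(_key_to_int(k) for k in keys)
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def child_rng(master_seed: int, *keys: int | str) -> np.random.Generator:
    """Independent Generator for the given (master seed, keys) pair."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=tuple(_key_to_int(k) for k in keys)
    )
    return np.random.default_rng(ss)
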