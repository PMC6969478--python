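"""Seed derivation.

All randomness in the package flows from a single user-facing integer seed.
Per-stage generators are derived by hashing the stage name (CRC-32) into a
``numpy.random.SeedSequence`` spawn key, so adding a stage never perturbs the
streams of existing stages and no global state is involved.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_int"]


def _keys(names: tuple) -> list[int]:
    out = []
    for name in names:
        if isinstance(name, (int, np.integer)):
            out.append(int(name) & 0x7FFFFFFF)
        else:
            out.append(zlib.crc32(str(name).encode("utf-8")))
    return out


def derive_rng(seed: int, *names) -> np.random.Generator:
    """Return a generator for stage ``names`` derived from the top-level seed."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=_keys(names))
    return np.random.default_rng(ss)


def derive_int(seed: int, *names) -> int:
    """A stable 31-bit integer sub-seed for stage ``names``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=_keys(names))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
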