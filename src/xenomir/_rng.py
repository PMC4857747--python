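"""Named-stream random number generators.

A single integer seed drives every stochastic component of the package.
Each generator owns a named stream so that, e.g., the Crt simulator and the
read simulator can be re-run independently with reproducible output.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the stream *name* derived from *seed*.

    The stream key is a CRC32 of the name, so the mapping is stable across
    sessions and Python hash randomization.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
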