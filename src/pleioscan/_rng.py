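"""Named, reproducible random substreams.

All stochastic steps in the package draw from a Generator obtained via
:func:`substream` so that one master seed determines every output
byte-for-byte, while independent stages (genotypes, traits, annotations,
permutations, model folds) never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` under `master_seed`.

    The stream identity is (master_seed, crc32(name)), so streams are stable
    across runs and platforms and distinct for distinct names.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key]))
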