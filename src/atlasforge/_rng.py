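"""Deterministic random-stream management.

All randomness in the package flows through one ``numpy`` generator scheme:
a root integer seed plus a stable per-label stream split, so that adding a
sample to a simulation never perturbs the streams of the existing samples.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "label_key"]


def label_key(label: str) -> int:
    """Stable 32-bit key for a string label (CRC32; platform-independent)."""
    return zlib.crc32(label.encode("utf-8")) & 0xFFFFFFFF


def stream(seed: int, *labels: str | int) -> np.random.Generator:
    """Return a generator for the stream identified by ``seed`` and labels.

    Distinct label tuples give statistically independent streams; the same
    tuple always gives the same stream.
    """
    keys = [label_key(x) if isinstance(x, str) else int(x) for x in labels]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), *keys])))
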