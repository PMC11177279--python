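"""Counter-based seed splitting.

All randomness in the package flows from a single integer seed. Independent
substreams are derived with :class:`numpy.random.SeedSequence` spawn keys so
that any subset of the simulation (one subject's EEG, one fold shuffle) is
reproducible on its own without generating everything before it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["substream", "subseed"]


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    String keys are hashed stably (by their UTF-8 bytes), so call sites can
    label streams (``substream(seed, "eeg", subject_idx)``) without
    coordinating integer namespaces.
    """
    ints = [_key_to_int(k) for k in keys]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), *ints])))


def subseed(seed: int, *keys: int | str) -> int:
    """A derived integer seed < 2**31 for APIs that take plain seeds."""
    ss = np.random.SeedSequence([int(seed), *[_key_to_int(k) for k in keys]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key)
    # stable, platform-independent string hash (FNV-1a, 32-bit)
    h = 2166136261
    for b in str(key).encode("utf-8"):
        h = ((h ^ b) * 16777619) & 0xFFFFFFFF
    return h
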