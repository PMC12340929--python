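"""Deterministic seed fan-out.

A single user-facing seed is expanded into independent per-generator
streams via :class:`numpy.random.SeedSequence` spawn keys.  Each named
stream gets a fixed integer key, so adding a new generator never shifts
the streams of existing ones, and the same (seed, name) pair always
yields bit-identical output.
"""

from __future__ import annotations

import numpy as np

# Fixed registry of stream keys.  Append only; never renumber.
_STREAM_KEYS = {
    "counts": 1,
    "markers": 2,
    "calcium": 3,
    "hypnogram": 4,
    "tissue": 5,
    "module_score": 6,
    "permutation": 7,
    "sections": 8,
    "fractionator": 9,
    "nucleator": 10,
}


def child_rng(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Return the RNG for stream ``name`` derived from the global ``seed``.

    ``index`` distinguishes repeated uses of the same stream (e.g. one
    stream per simulated slice or per permutation replicate).
    """
    if name not in _STREAM_KEYS:
        raise KeyError(f"unknown RNG stream {name!r}; register it in _STREAM_KEYS")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAM_KEYS[name], int(index)))
    return np.random.default_rng(ss)


def child_seed(seed: int, name: str, index: int = 0) -> int:
    """A plain integer seed (< 2**31) derived from the named stream."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAM_KEYS[name], int(index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
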