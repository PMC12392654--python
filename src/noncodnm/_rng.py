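"""Named, seed-stable random streams and a counter-based per-position hash.

A single integer seed drives one independent stream per generator stage, keyed
by a stage name, so adding a new stage never perturbs the draws of an existing
one.  Per-position quantities (functional scores) come from a stateless
splitmix64 hash of (seed, stage, chromosome, position), which makes them
reproducible and cheap to evaluate lazily over arbitrarily large coordinates
without materialising a genome-wide table.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


def stream(seed: int, name: str) -> np.random.Generator:
    """Return an independent PCG64 stream for stage ``name`` under ``seed``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _splitmix64(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        x = (x + np.uint64(0x9E3779B97F4A7C15)) & _MASK
        x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK
        x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK
        return x ^ (x >> np.uint64(31))


def position_u01(seed: int, name: str, chrom_index: int, pos: np.ndarray) -> np.ndarray:
    """Deterministic uniform(0,1) variate for each 0-based position.

    ``pos`` may be a scalar or array; the result depends only on
    (seed, name, chrom_index, position).
    """
    key = np.uint64((int(seed) & 0x7FFFFFFF) ^ (zlib.crc32(name.encode()) << 31))
    p = np.asarray(pos, dtype=np.uint64)
    mixed = _splitmix64(p ^ (np.uint64(chrom_index + 1) << np.uint64(48)) ^ key)
    return mixed.astype(np.float64) / float(2**64)
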