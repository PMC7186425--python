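"""Named, independently seeded random streams.

One master seed fully determines a replicate.  Every stochastic component
(founder history, base sampling, QTL effects, the breeding loop) draws from
its own named stream derived from the master seed, so that two scenarios run
with the same master seed share their founder and base-population randomness
and diverge only where their policies differ.
"""

from __future__ import annotations

import numpy as np

# registry of stream names -> fixed spawn keys; append-only to keep
# reproducibility across versions
_STREAMS = {
    "map": 0,
    "founders": 1,
    "base": 2,
    "effects": 3,
    "engine": 4,
    "misc": 5,
}


def stream(master_seed: int, name: str, extra: int = 0) -> np.random.Generator:
    """Return the named random stream for a master seed.

    ``extra`` sub-keys a stream (e.g. one per replicate) without collisions
    between names.
    """
    if name not in _STREAMS:
        raise KeyError(f"unknown stream {name!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(int(master_seed),
                                spawn_key=(_STREAMS[name], int(extra)))
    return np.random.default_rng(ss)


def replicate_seed(master_seed: int, replicate: int, cell: int = 0) -> int:
    """Derive a per-replicate master seed below 2**31, stable in the cell
    and replicate indices and insensitive to the order replicates run in."""
    ss = np.random.SeedSequence(int(master_seed),
                                spawn_key=(982451653, int(cell), int(replicate)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
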