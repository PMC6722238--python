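"""Counter-based uniform draws keyed by simulation coordinates.

Both comparison arms of the paired simulation must see *identical* randomness
for every (person, day) onset decision and every (person, episode) resource
decision, regardless of how the arms diverge.  Stateful generators cannot give
that guarantee, so every draw here is a pure function of
``(seed, stream, *keys)`` built on the splitmix64 finalizer, which has full
avalanche and passes standard equidistribution batteries.  Draws are
reproducible across platforms and independent of evaluation order.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_INV_2_53 = 2.0 ** -53


class Stream(IntEnum):
    """Independent draw streams of the simulation."""

    ONSET = 1
    UPTAKE = 2
    DURATION = 3
    ANTIBIOTIC = 4
    OTHER_MED = 5
    ABSENCE_ANY = 6
    ABSENCE_AMOUNT = 7


def _splitmix64(z: np.ndarray) -> np.ndarray:
    z = z + _GAMMA
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


def keyed_uniform(seed: int, stream: int, *keys) -> np.ndarray:
    """Uniform(0, 1) draws determined entirely by ``(seed, stream, keys)``.

    Integer keys (scalars or arrays, broadcast together) index the draw:
    e.g. ``(person_id, day)`` for onset decisions or ``(person_id,
    episode_index)`` for episode-level resources.  Identical keys always
    yield identical values, which is what makes the paired-arm design work.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    with np.errstate(over="ignore"):  # uint64 arithmetic wraps by design
        h = _splitmix64(np.asarray(seed, dtype=np.uint64))
        h = _splitmix64(h ^ (np.asarray(int(stream), dtype=np.uint64) * _GAMMA))
        for key in keys:
            k = np.asarray(key)
            if not np.issubdtype(k.dtype, np.integer):
                raise TypeError("draw keys must be integers")
            if np.any(k < 0):
                raise ValueError("draw keys must be non-negative")
            h = _splitmix64(h ^ (k.astype(np.uint64) * _MIX1))
        return (h >> np.uint64(11)).astype(np.float64) * _INV_2_53
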