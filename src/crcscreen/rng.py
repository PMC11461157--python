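"""Named, seedable random substreams.

All stochastic draws in the simulator are keyed by (seed, stream, person,
...context) rather than consumed from one sequential generator.  This gives
three properties the analysis relies on:

* person i's history is independent of cohort size (substream per person);
* a strategy overlay draw at a given exam age is identical across strategies
  that reach the same exam (common random numbers), so between-strategy
  contrasts are pathwise paired;
* reruns with the same seed are bit-reproducible.

Per-event uniforms use a splitmix64-style avalanche hash over the key tuple;
bulk per-person draws use a counter-based Philox generator keyed the same
way.
"""

from __future__ import annotations

import numpy as np

_MASK64 = (1 << 64) - 1

# stream codes
STREAM_NATHIST = 1
EV_SCREEN = 11
EV_COLO_LESION = 12
EV_COLO_COMPLICATION = 13
STREAM_RF = 21


def _splitmix(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = (x ^ (x >> 30)) * 0xBF58476D1CE4E5B9 & _MASK64
    z = (z ^ (z >> 27)) * 0x94D049BB133111EB & _MASK64
    return z ^ (z >> 31)


def hash_key(*keys: int) -> int:
    """Mix an arbitrary tuple of integers into one 64-bit value."""
    h = 0x8422A9C1957F4D0E
    for k in keys:
        h = _splitmix(h ^ (int(k) & _MASK64))
    # one extra round so a trailing zero key still perturbs
    return _splitmix(h)


def keyed_uniform(*keys: int) -> float:
    """Deterministic U(0,1) draw for a key tuple (53-bit mantissa)."""
    return (hash_key(*keys) >> 11) * (1.0 / (1 << 53))


def keyed_generator(*keys: int) -> np.random.Generator:
    """Counter-based generator whose stream is a pure function of the keys."""
    return np.random.Generator(np.random.Philox(key=hash_key(*keys)))


def age_key(age: float) -> int:
    """Quantize an event age to 1/512-year ticks for use in a key tuple."""
    return int(round(age * 512.0))
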