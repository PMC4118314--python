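"""Common-random-number streams for paired cohort comparisons.

Every stochastic decision in the simulation has a fixed *slot*.  Uniform
draws are generated from counter-based Philox streams keyed by
``(master seed, age, slot)``; a woman's draw is the element at her person
index within that stream.  The contract: identical (seed, person index,
age, slot) yields the identical uniform regardless of risk group, cohort
size beyond the person index, or parameter values.  Paired runs of two risk
groups therefore differ only through the parameters — the common-random-
numbers variance-reduction scheme used for excess estimation — and the
vectorized cohort engine and the per-woman reference engine consume exactly
the same numbers.
"""

from __future__ import annotations

import numpy as np

# decision-slot order within a person-year (fracture-type slots follow the
# FractureType ordering; changing any of this changes every simulated history)
SLOT_OSTEO_ONSET = 0
SLOT_FRACTURE_BASE = 1          # 1..6, + FractureType
SLOT_HOSPITALIZATION_BASE = 7   # 7..12
SLOT_REHAB_BASE = 13            # 13..18
SLOT_NH_FRACTURE = 19
SLOT_NH_BACKGROUND = 20
SLOT_NH_COUNTERFACTUAL = 21
SLOT_SURVIVAL = 22
SLOT_PRELOAD_OSTEO = 23         # drawn once at the start age
SLOT_PRELOAD_PREVFX = 24

_SLOT_STRIDE = 32  # slots per age in the key space; slot ids must stay < 32

MAX_SEED = 2**31


def _generator(seed: int, age: int, slot: int) -> np.random.Generator:
    if not 0 <= seed < MAX_SEED:
        raise ValueError(f"master seed must lie in [0, {MAX_SEED})")
    if not 0 <= slot < _SLOT_STRIDE:
        raise ValueError("slot out of range")
    key = np.array([seed, age * _SLOT_STRIDE + slot], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


def uniforms(seed: int, age: int, slot: int, n: int) -> np.ndarray:
    """The first `n` uniforms of the (seed, age, slot) stream, person i at index i."""
    return _generator(seed, age, slot).random(n)


def person_uniform(seed: int, age: int, slot: int, person_index: int) -> float:
    """The single uniform of one woman — element `person_index` of the stream.

    O(person_index) per call; intended for the per-woman reference engine and
    for tests, not for large cohorts (those use :func:`uniforms`).
    """
    return float(_generator(seed, age, slot).random(person_index + 1)[-1])
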