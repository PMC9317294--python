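"""Deterministic seed fan-out.

A single master seed drives the whole pipeline.  Each stage draws its own
child seed through a counter scheme: child ``i`` is the ``i``-th 32-bit word
of ``numpy.random.SeedSequence(master)``, masked to a non-negative int31 so
it is accepted by every downstream RNG API.  Stages therefore get mutually
independent streams, and any single stage can be replayed in isolation from
``(master_seed, stage_name)`` alone.
"""

from __future__ import annotations

import numpy as np

# Fixed stage -> counter table.  Appending new stages is safe; reordering is
# not (it would silently change every downstream stream).
STAGE_COUNTERS = {
    "fixtures": 0,
    "split": 1,
    "augment": 2,
    "extract": 3,
    "select": 4,
    "train": 5,
    "evaluate": 6,
}


def child_seed(master_seed: int, stage: int | str) -> int:
    """Derive the child seed for *stage* (name or raw counter) from the master."""
    counter = STAGE_COUNTERS[stage] if isinstance(stage, str) else int(stage)
    if counter < 0:
        raise ValueError(f"stage counter must be non-negative, got {counter}")
    words = np.random.SeedSequence(int(master_seed)).generate_state(counter + 1)
    return int(words[counter] & 0x7FFFFFFF)


def stage_rng(master_seed: int, stage: int | str) -> np.random.Generator:
    """A Generator seeded with the stage's child seed."""
    return np.random.default_rng(child_seed(master_seed, stage))
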