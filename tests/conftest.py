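"""Shared fixtures: seeded random sequence generators.

Random sequences for oracle-equivalence tests are drawn from a CAG-biased
alphabet mixture so that repeat tracts of nontrivial length actually occur;
uniform draws alone almost never produce a tract worth disagreeing about.
"""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220930)


def random_repeat_rich_sequence(rng: np.random.Generator,
                                max_len: int = 60,
                                unit: str = "CAG") -> str:
    """Sequence mixing uniform bases with embedded partial repeat runs."""
    length = int(rng.integers(6, max_len + 1))
    out: list[str] = []
    while len(out) < length:
        if rng.random() < 0.4:
            run = int(rng.integers(2, 15))
            phase = int(rng.integers(0, 3))
            out.extend(unit[(phase + k) % 3] for k in range(run))
        else:
            out.extend(rng.choice(list("ACGTN"), size=int(rng.integers(1, 6)),
                                  p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    return "".join(out[:length])
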