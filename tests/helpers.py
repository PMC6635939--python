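"""Shared plain-function test helpers (kept outside conftest so test modules
can import them directly)."""
from __future__ import annotations

import numpy as np

from phylopop import Alignment


def random_alignment(rng: np.random.Generator, n: int, k: int) -> Alignment:
    """Uniform random unambiguous alignment."""
    bases = np.array(list("ACGT"))
    seqs = tuple("".join(bases[rng.integers(0, 4, size=k)]) for _ in range(n))
    return Alignment(tuple(f"s{i}" for i in range(n)), seqs)
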