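"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results by naive enumeration so the
library's scanning and classification code is checked against logic that
shares nothing with it.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def naive_rore_scan(seq: str) -> list[tuple[int, str, str]]:
    """Enumerate every 6-window on both strands; (1-based start, strand,
    word on hit strand)."""
    hits = []
    for i in range(len(seq) - 5):
        w = seq[i : i + 6]
        if w in ("AGGTCA", "GGGTCA"):
            hits.append((i + 1, "+", w))
        rc = naive_revcomp(w)
        if rc in ("AGGTCA", "GGGTCA") and "N" not in w:
            hits.append((i + 1, "-", rc))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def naive_lcs_scan(utr: str, target_word: str, max_mm: int) -> list[tuple[int, int]]:
    """(1-based start, mismatches) of every window within Hamming
    distance max_mm of the seed-complement word."""
    k = len(target_word)
    out = []
    for i in range(len(utr) - k + 1):
        w = utr[i : i + k]
        if "N" in w:
            continue
        mm = sum(a != b for a, b in zip(w, target_word))
        if mm <= max_mm:
            out.append((i + 1, mm))
    return out


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
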