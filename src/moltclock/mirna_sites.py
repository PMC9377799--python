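"""let-7 consensus site (LCS) detection in 3' UTRs.

A *let-7* consensus site is a stretch of a 3' UTR that is the Watson-Crick
complement of the microRNA seed (mature nt 2-8 by default), allowing at most
one mismatched nucleotide within the seed. Only the sense (mRNA) strand is
scanned. G:U wobble pairs are not considered: the rule is sequence
complementarity, not hybridization energy, and no free-energy filtering is
applied.

For each site a count of Watson-Crick pairs between the non-seed 3' portion
of the microRNA and the UTR immediately 5' of the seed match is reported, as
a coarse descriptor of supplementary pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from .sequence_scan import SequenceRecord, reverse_complement

__all__ = [
    "MatureMirna",
    "SeedSite",
    "UtrRecord",
    "CELEGANS_LET7",
    "seed_target_words",
    "find_lcs",
    "expected_lcs_count",
    "is_lcs_enriched",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class MatureMirna:
    """A mature microRNA, stored 5'->3' with U mapped to T.

    ``seed_span`` is the 1-based inclusive span of the seed within the
    mature sequence; the default (2, 8) is the canonical 7-mer seed.
    """

    name: str
    sequence: str
    seed_span: tuple[int, int] = (2, 8)

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if not set(seq) <= set(_BASES):
            raise ValueError(f"mature miRNA {self.name!r} has non-RNA/DNA characters")
        if not 18 <= len(seq) <= 25:
            raise ValueError(
                f"mature miRNA length must be 18-25 nt, got {len(seq)}"
            )
        lo, hi = self.seed_span
        if not (1 <= lo <= hi <= len(seq)):
            raise ValueError("seed_span outside the mature sequence")
        object.__setattr__(self, "sequence", seq)

    @property
    def seed(self) -> str:
        lo, hi = self.seed_span
        return self.sequence[lo - 1 : hi]

    @property
    def nonseed_3prime(self) -> str:
        """Mature sequence 3' of the seed (nt seed_end+1 .. end)."""
        return self.sequence[self.seed_span[1] :]


#: Mature C. elegans let-7 (identical in sequence to human let-7a).
CELEGANS_LET7 = MatureMirna("cel-let-7", "UGAGGUAGUAGGUUGUAUAGUU")


@dataclass(frozen=True)
class SeedSite:
    """One seed-complementary site within a UTR (1-based, inclusive)."""

    utr_id: str
    start: int
    end: int
    seed_mismatches: int
    perfect_seed: bool
    paired_3prime: int

    def __post_init__(self) -> None:
        if self.perfect_seed != (self.seed_mismatches == 0):
            raise ValueError("perfect_seed inconsistent with seed_mismatches")


@dataclass(frozen=True)
class UtrRecord:
    """A 3' UTR on the sense (mRNA) strand; position 1 is the first base
    after the stop codon."""

    gene: str
    sequence: str
    species: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if not set(seq) <= set("ACGTN"):
            raise ValueError(f"UTR {self.gene!r} has non-DNA characters")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def seed_target_words(mirna: MatureMirna, max_mismatch: int = 1) -> set[str]:
    """DNA words a UTR site may take: the seed's reverse complement plus,
    for ``max_mismatch`` = 1, every single-substitution variant."""
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    exact = reverse_complement(mirna.seed)
    words = {exact}
    if max_mismatch == 1:
        for pos, base in product(range(len(exact)), _BASES):
            if base != exact[pos]:
                words.add(exact[:pos] + base + exact[pos + 1 :])
    return words


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _pairs_3prime(utr_seq: str, site_start0: int, mirna: MatureMirna) -> int:
    """Watson-Crick pairs between the miRNA 3' region and the UTR flank.

    The seed match pairs miRNA nt 2..8 with the site; the remainder of the
    mature miRNA (3' of the seed) would pair with UTR bases immediately 5'
    of the site. Counts exact complement positions in that aligned flank.
    """
    flank_target = reverse_complement(mirna.nonseed_3prime)
    flank_len = len(flank_target)
    lo = site_start0 - flank_len
    if lo < 0:
        flank_target = flank_target[-site_start0:] if site_start0 else ""
        lo = 0
    window = utr_seq[lo:site_start0]
    return sum(x == y for x, y in zip(window, flank_target))


def find_lcs(
    utr: UtrRecord, mirna: MatureMirna = CELEGANS_LET7, max_mismatch: int = 1
) -> list[SeedSite]:
    """All seed-complementary sites in the UTR with <= max_mismatch
    substitutions in the seed match, sorted by start position."""
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    target = reverse_complement(mirna.seed)
    k = len(target)
    seq = utr.sequence
    sites: list[SeedSite] = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        mm = _hamming(window, target)
        if mm <= max_mismatch:
            sites.append(
                SeedSite(
                    utr_id=utr.gene,
                    start=i + 1,
                    end=i + k,
                    seed_mismatches=mm,
                    perfect_seed=mm == 0,
                    paired_3prime=_pairs_3prime(seq, i, mirna),
                )
            )
    return sites


def expected_lcs_count(
    utr_length: int, max_mismatch: int = 1, seed_length: int = 7
) -> float:
    """Chance expectation of LCS counts on a single strand under uniform
    base composition: windows x admissible words / 4**seed_length."""
    if utr_length < 0:
        raise ValueError("utr_length must be non-negative")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    windows = max(0, utr_length - seed_length + 1)
    n_words = 1 + (3 * seed_length if max_mismatch == 1 else 0)
    return windows * n_words / 4**seed_length


def is_lcs_enriched(observed: int, expected: float) -> bool:
    """Sites detected more often than, or equal to, chance expectation
    (non-strict, unlike the RORE rule)."""
    if observed < 0:
        raise ValueError("observed must be non-negative")
    return observed >= expected
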