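"""Evidence integration: calling clock-controlled genes (CCGs) as targets
of NHR-23, the let-7 family, both, or neither.

A gene is called an NHR-23 target when at least two of three criteria hold:
an NHR-23 ChIP-seq peak (Z >= 2) over its upstream region or first intron,
more ROREs in that region than expected by chance, and transcript levels at
least 1.2-fold reduced upon nhr-23 knockdown. A let-7 target must satisfy
both of: ALG-1 iCLIP binding of the 3' UTR on the coding strand, and LCS
counts at or above chance expectation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .mirna_sites import (
    CELEGANS_LET7,
    MatureMirna,
    UtrRecord,
    expected_lcs_count,
    find_lcs,
    is_lcs_enriched,
)
from .sequence_scan import (
    BackgroundModel,
    SequenceRecord,
    expected_count,
    is_rore_enriched,
    scan_rore,
)

__all__ = [
    "CcgEvidence",
    "TargetCall",
    "VennCounts",
    "CHIP_Z_THRESHOLD",
    "KNOCKDOWN_FOLD_THRESHOLD",
    "classify_nhr23",
    "classify_let7",
    "classify",
    "tabulate",
    "derive_evidence",
    "resolve_evidence",
    "classify_cohort",
]

logger = logging.getLogger(__name__)

CHIP_Z_THRESHOLD = 2.0
KNOCKDOWN_FOLD_THRESHOLD = 1.2

EVIDENCE_COLUMNS = (
    "gene_id",
    "oscillatory",
    "chip_peak",
    "rore_enriched",
    "knockdown_reduced",
    "alg1_bound",
    "lcs_enriched",
)


@dataclass(frozen=True)
class CcgEvidence:
    """Per-gene boolean evidence flags (tri-state on input; ``None`` means
    unknown and must be resolved before classification)."""

    gene_id: str
    oscillatory: Optional[bool] = True
    chip_peak: Optional[bool] = None
    rore_enriched: Optional[bool] = None
    knockdown_reduced: Optional[bool] = None
    alg1_bound: Optional[bool] = None
    lcs_enriched: Optional[bool] = None

    def unresolved_flags(self) -> list[str]:
        return [
            name
            for name in EVIDENCE_COLUMNS[1:]
            if getattr(self, name) is None
        ]


class TargetCall(str, Enum):
    """Four-way target classification of one CCG."""

    BOTH = "both"
    NHR23_ONLY = "nhr23_only"
    LET7_ONLY = "let7_only"
    NEITHER = "neither"


@dataclass(frozen=True)
class VennCounts:
    """Category counts for a classified cohort, with percentages rounded
    to the nearest integer for display."""

    both: int
    nhr23_only: int
    let7_only: int
    neither: int

    @property
    def total(self) -> int:
        return self.both + self.nhr23_only + self.let7_only + self.neither

    @property
    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            raise ValueError("percentages undefined for an empty cohort")
        return {
            call.value: round(100 * getattr(self, call.value) / self.total)
            for call in TargetCall
        }


def resolve_evidence(evidence: CcgEvidence, strict: bool = False) -> CcgEvidence:
    """Resolve unknown (None) flags to False, logging a warning; in strict
    mode unknowns raise instead."""
    missing = evidence.unresolved_flags()
    if not missing:
        return evidence
    if strict:
        raise ValueError(
            f"gene {evidence.gene_id!r} has unresolved flags: {missing}"
        )
    logger.warning(
        "gene %r: unresolved flags %s resolved to False", evidence.gene_id, missing
    )
    resolved = {name: bool(getattr(evidence, name)) for name in EVIDENCE_COLUMNS[1:]}
    return CcgEvidence(evidence.gene_id, **resolved)


def classify_nhr23(evidence: CcgEvidence) -> bool:
    """NHR-23 target: at least 2 of {chip_peak, rore_enriched,
    knockdown_reduced}."""
    flags = (evidence.chip_peak, evidence.rore_enriched, evidence.knockdown_reduced)
    if any(f is None for f in flags):
        raise ValueError(f"gene {evidence.gene_id!r}: flags not resolved")
    return sum(bool(f) for f in flags) >= 2


def classify_let7(evidence: CcgEvidence) -> bool:
    """let-7 target: ALG-1 bound AND LCS-enriched (both criteria)."""
    if evidence.alg1_bound is None or evidence.lcs_enriched is None:
        raise ValueError(f"gene {evidence.gene_id!r}: flags not resolved")
    return bool(evidence.alg1_bound) and bool(evidence.lcs_enriched)


def classify(evidence: CcgEvidence) -> TargetCall:
    """Cross the two boolean calls into the four Venn categories."""
    nhr23 = classify_nhr23(evidence)
    let7 = classify_let7(evidence)
    if nhr23 and let7:
        return TargetCall.BOTH
    if nhr23:
        return TargetCall.NHR23_ONLY
    if let7:
        return TargetCall.LET7_ONLY
    return TargetCall.NEITHER


def tabulate(calls: Iterable[TargetCall]) -> VennCounts:
    """Count calls per category. An empty input yields zero counts (the
    percentage accessor then raises)."""
    counts = Counter(TargetCall(c) for c in calls)
    return VennCounts(
        both=counts[TargetCall.BOTH],
        nhr23_only=counts[TargetCall.NHR23_ONLY],
        let7_only=counts[TargetCall.LET7_ONLY],
        neither=counts[TargetCall.NEITHER],
    )


def derive_evidence(
    gene_id: str,
    promoter: Optional[SequenceRecord] = None,
    utr: Optional[UtrRecord] = None,
    chip_z: Optional[float] = None,
    knockdown_fold: Optional[float] = None,
    alg1_bound: Optional[bool] = None,
    background: Optional[BackgroundModel] = None,
    mirna: MatureMirna = CELEGANS_LET7,
    max_mismatch: int = 1,
    oscillatory: Optional[bool] = True,
) -> CcgEvidence:
    """Derive the evidence flags for one gene from primary inputs.

    Sequence-derived flags use the module rules: RORE enrichment is strict
    (> chance), LCS enrichment non-strict (>= chance). ChIP Z-scores and
    knockdown fold changes are thresholded inclusively (Z >= 2, >= 1.2-fold
    reduced). Missing inputs leave the flag unresolved with a warning.
    """
    background = background or BackgroundModel()

    rore_enriched: Optional[bool] = None
    if promoter is not None:
        observed = len(scan_rore(promoter))
        rore_enriched = is_rore_enriched(
            observed, expected_count(len(promoter), background)
        )
    else:
        logger.warning("gene %r: no promoter sequence; rore_enriched unresolved", gene_id)

    lcs_enriched: Optional[bool] = None
    if utr is not None:
        seed_len = mirna.seed_span[1] - mirna.seed_span[0] + 1
        observed = len(find_lcs(utr, mirna, max_mismatch))
        lcs_enriched = is_lcs_enriched(
            observed, expected_lcs_count(len(utr), max_mismatch, seed_len)
        )
    else:
        logger.warning("gene %r: no UTR sequence; lcs_enriched unresolved", gene_id)

    chip_peak = None if chip_z is None else chip_z >= CHIP_Z_THRESHOLD
    knockdown_reduced = (
        None if knockdown_fold is None else knockdown_fold >= KNOCKDOWN_FOLD_THRESHOLD
    )

    return CcgEvidence(
        gene_id=gene_id,
        oscillatory=oscillatory,
        chip_peak=chip_peak,
        rore_enriched=rore_enriched,
        knockdown_reduced=knockdown_reduced,
        alg1_bound=alg1_bound,
        lcs_enriched=lcs_enriched,
    )


def classify_cohort(
    cohort: Sequence[CcgEvidence], strict: bool = False
) -> list[TargetCall]:
    """Resolve and classify a whole cohort."""
    return [classify(resolve_evidence(ev, strict=strict)) for ev in cohort]
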