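"""File formats: FASTA, BED6, TSV reports, YAML stage annotations.

TSV files are tab-delimited UTF-8 with a header row and "." for missing
values. Internal coordinates are 1-based inclusive; BED6 export converts
to the standard 0-based half-open convention.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .actogram import ActivityState, AnimalTrack
from .mirna_sites import SeedSite
from .sequence_scan import MotifHit, RegionScan, SequenceRecord
from .target_classify import EVIDENCE_COLUMNS, CcgEvidence
from .waveform import StageWindows

__all__ = [
    "read_fasta",
    "write_fasta",
    "hits_to_bed6",
    "write_bed6",
    "sites_to_frame",
    "region_scans_to_frame",
    "evidence_to_frame",
    "read_evidence_tsv",
    "write_tsv",
    "read_stage_windows_yaml",
    "write_stage_windows_yaml",
    "read_actogram_tsv",
    "write_actogram_tsv",
]

MISSING = "."


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Residues are uppercased; duplicate record ids are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def hits_to_bed6(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Motif hits as BED6 (0-based half-open, score column unused)."""
    return pd.DataFrame(
        {
            "chrom": [h.seq_id for h in hits],
            "chromStart": [h.start - 1 for h in hits],
            "chromEnd": [h.end for h in hits],
            "name": [h.word for h in hits],
            "score": [0] * len(hits),
            "strand": [h.strand for h in hits],
        }
    )


def write_bed6(hits: Sequence[MotifHit], path: str | Path) -> None:
    hits_to_bed6(hits).to_csv(path, sep="\t", header=False, index=False)


def sites_to_frame(sites: Sequence[SeedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "utr_id": s.utr_id,
                "start": s.start,
                "end": s.end,
                "seed_mismatches": s.seed_mismatches,
                "perfect_seed": s.perfect_seed,
                "paired_3prime": s.paired_3prime,
            }
            for s in sites
        ],
        columns=["utr_id", "start", "end", "seed_mismatches", "perfect_seed", "paired_3prime"],
    )


def region_scans_to_frame(scans: Sequence[RegionScan]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "length": r.length,
                "observed": r.observed,
                "expected": r.expected,
                "enriched": r.enriched,
            }
            for r in scans
        ],
        columns=["region_id", "length", "observed", "expected", "enriched"],
    )


def evidence_to_frame(cohort: Sequence[CcgEvidence]) -> pd.DataFrame:
    rows = []
    for ev in cohort:
        row = {"gene_id": ev.gene_id}
        for col in EVIDENCE_COLUMNS[1:]:
            row[col] = getattr(ev, col)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS))


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_evidence_tsv(path: str | Path) -> list[CcgEvidence]:
    """Read an evidence table; "." cells become unresolved (None) flags."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=True)
    missing_cols = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"evidence table missing columns: {sorted(missing_cols)}")
    cohort = []
    for _, row in df.iterrows():
        flags = {}
        for col in EVIDENCE_COLUMNS[1:]:
            val = row[col]
            flags[col] = None if pd.isna(val) else _parse_bool(val)
        cohort.append(CcgEvidence(gene_id=str(row["gene_id"]), **flags))
    return cohort


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        low = value.strip().lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot parse boolean {value!r}")
    return bool(value)


def write_stage_windows_yaml(
    windows: dict[str, StageWindows], path: str | Path
) -> None:
    """Per-genotype lethargus annotations."""
    payload = {
        genotype: {
            "lethargi": [[float(a), float(b)] for a, b in w.lethargi],
            "labels": list(w.labels),
        }
        for genotype, w in windows.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_stage_windows_yaml(path: str | Path) -> dict[str, StageWindows]:
    payload = yaml.safe_load(Path(path).read_text())
    return {
        genotype: StageWindows(
            lethargi=tuple(tuple(pair) for pair in spec["lethargi"]),
            labels=tuple(spec.get("labels", ())),
        )
        for genotype, spec in payload.items()
    }


def write_actogram_tsv(tracks: Sequence[AnimalTrack], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        index_events = {idx: kind for kind, idx in tr.events.items()}
        for i, state in enumerate(tr.states):
            rows.append(
                {
                    "animal_id": tr.animal_id,
                    "genotype": tr.genotype,
                    "t_index": i,
                    "state": state.value,
                    "annotation": index_events.get(i, MISSING),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_actogram_tsv(
    path: str | Path, sample_interval_h: float = 1.0
) -> list[AnimalTrack]:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING])
    tracks = []
    for (animal_id, genotype), sub in df.groupby(["animal_id", "genotype"], sort=False):
        sub = sub.sort_values("t_index")
        events = {}
        for _, row in sub.iterrows():
            if isinstance(row.get("annotation"), str):
                events[row["annotation"]] = int(row["t_index"])
        tracks.append(
            AnimalTrack(
                animal_id=str(animal_id),
                genotype=str(genotype),
                states=tuple(ActivityState(s) for s in sub["state"]),
                sample_interval_h=sample_interval_h,
                events=events,
            )
        )
    return tracks
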