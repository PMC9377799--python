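#!/usr/bin/env python
"""Scan the synthetic promoters for ROREs and the UTRs for let-7 sites.

Reads results/synthetic/{promoters,utrs}.fa, writes BED6 hits, a per-region
enrichment report, and a seed-site table; prints what was found relative to
chance expectation.
"""

from pathlib import Path

from moltclock import io
from moltclock.mirna_sites import UtrRecord, expected_lcs_count, find_lcs, is_lcs_enriched
from moltclock.sequence_scan import BackgroundModel, scan_region, scan_rore

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "scan"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    promoters = io.read_fasta(BASE / "synthetic" / "promoters.fa")
    model = BackgroundModel("uniform")

    all_hits, scans = [], []
    for rec in promoters:
        hits = scan_rore(rec)
        all_hits.extend(hits)
        scan = scan_region(rec, model)
        scans.append(scan)
        print(
            f"{rec.id}: {scan.observed} ROREs in {scan.length} nt "
            f"(expected {scan.expected:.3f} by chance) -> "
            f"{'enriched' if scan.enriched else 'not enriched'}"
        )
    io.write_bed6(all_hits, OUT / "rore_hits.bed")
    io.write_tsv(io.region_scans_to_frame(scans), OUT / "rore_regions.tsv")

    utrs = io.read_fasta(BASE / "synthetic" / "utrs.fa")
    frames = []
    for rec in utrs:
        utr = UtrRecord(rec.id, rec.residues)
        sites = find_lcs(utr, max_mismatch=1)
        expected = expected_lcs_count(len(utr), 1, 7)
        perfect = [s for s in sites if s.perfect_seed]
        print(
            f"{rec.id}: {len(sites)} seed sites ({len(perfect)} perfect) in "
            f"{len(utr)} nt; chance expectation {expected:.2f}; "
            f"let-7 criterion {'met' if is_lcs_enriched(len(sites), expected) else 'not met'}"
        )
        frames.append(io.sites_to_frame(sites))
    import pandas as pd

    io.write_tsv(pd.concat(frames, ignore_index=True), OUT / "lcs_sites.tsv")
    print(f"reports under {OUT}")


if __name__ == "__main__":
    main()
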