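#!/usr/bin/env python
"""Interval analytics on the synthetic behavioral cohorts.

Computes per-genotype active / lethargus / wake-to-wake summaries with
pairwise comparisons, and classifies the fates of simulated quiescent
adults (supernumerary molt vs transient quiescence vs death).
"""

from collections import Counter
from pathlib import Path

from moltclock import io, simulate
from moltclock.actogram import classify_adult_fate, cohort_summary

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tracks = io.read_actogram_tsv(BASE / "synthetic" / "actograms.tsv")
    out = BASE / "behavior"
    out.mkdir(parents=True, exist_ok=True)

    for metric in ("active_interval_h", "lethargus_interval_h", "wake_to_wake_h"):
        summary, comparisons = cohort_summary(tracks, metric)
        io.write_tsv(summary, out / f"{metric}_summary.tsv")
        io.write_tsv(comparisons, out / f"{metric}_comparisons.tsv")
        line = ", ".join(
            f"{r.genotype} {r.mean:.1f} ± {r.sd:.1f} h" for r in summary.itertuples()
        )
        print(f"{metric}: {line}")

    fate_tracks, planted = simulate.gen_adult_fate_tracks(n_animals=34, seed=1)
    fates = [classify_adult_fate(t).value for t in fate_tracks]
    counts = Counter(fates)
    pct = 100 * counts["supernumerary_molt"] / len(fates)
    print(
        f"adult fates (n={len(fates)}): {dict(counts)}; "
        f"{pct:.0f}% supernumerary molts; matches planted fates: {fates == planted}"
    )


if __name__ == "__main__":
    main()
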