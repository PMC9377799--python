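"""Synthetic-data generators: determinism, planted ground truth, and
agreement between planted parameters and analytic expectation."""

import numpy as np
import pytest

from moltclock.mirna_sites import CELEGANS_LET7
from moltclock.quantify import chip_fold_enrichment, relative_expression
from moltclock.sequence_scan import SequenceRecord, scan_rore
from moltclock.simulate import (
    gen_actograms,
    gen_ccg_cohort,
    gen_ccg_cohort_exact,
    gen_chip,
    gen_expression,
    gen_qpcr,
    gen_sequence,
)
from moltclock.target_classify import TargetCall, classify, tabulate
from moltclock.actogram import wake_to_wake


def test_same_seed_reproduces_outputs_exactly():
    a, _ = gen_sequence(500, gc=0.42, seed=7)
    b, _ = gen_sequence(500, gc=0.42, seed=7)
    assert a.residues == b.residues
    ta, _ = gen_actograms(n_animals=5, seed=7)
    tb, _ = gen_actograms(n_animals=5, seed=7)
    assert [t.states for t in ta] == [t.states for t in tb]
    sa, _, _ = gen_expression(noise_sd=0.3, seed=7)
    sb, _, _ = gen_expression(noise_sd=0.3, seed=7)
    assert sa.value == sb.value


def test_planted_rore_is_found_where_planted():
    rec, truth = gen_sequence(1000, seed=1, plant=[("AGGTCA", 101)])
    assert truth["planted"][0]["start"] == 101
    assert any(h.start == 101 and h.strand == "+" for h in scan_rore(rec))


def test_motif_free_sequence_has_no_rores():
    rec, _ = gen_sequence(10_000, seed=2, motif_free=True)
    assert scan_rore(rec) == []


def test_overlapping_plants_rejected():
    with pytest.raises(ValueError):
        gen_sequence(100, plant=[("AGGTCA", 10), ("GGGTCA", 12)])


def test_at_rich_sequence_has_depressed_rore_density():
    gc = 0.35
    rec, _ = gen_sequence(100_000, gc=gc, seed=3)
    observed = len(scan_rore(rec))
    # composition-adjusted expectation for (A|G)GGTCA on both strands
    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    per_word = lambda w: np.prod([p[c] for c in w])
    windows = len(rec) - 5
    expected = windows * 2 * (per_word("AGGTCA") + per_word("GGGTCA"))
    assert observed < 0.977 / 1000 * len(rec)  # below the uniform rate
    assert abs(observed - expected) < 4 * np.sqrt(expected)


def test_cohort_extremes():
    probs_on = {f: 1.0 for f in ("chip_peak", "rore_enriched", "knockdown_reduced", "alg1_bound", "lcs_enriched")}
    cohort, calls = gen_ccg_cohort(10, probs_on, seed=4)
    assert all(c is TargetCall.BOTH for c in calls)
    probs_off = {k: 0.0 for k in probs_on}
    _, calls = gen_ccg_cohort(10, probs_off, seed=4)
    assert all(c is TargetCall.NEITHER for c in calls)


def test_random_cohort_truth_matches_classifier(rng):
    cohort, truth = gen_ccg_cohort(100, seed=5)
    assert [classify(ev) for ev in cohort] == truth


def test_exact_cohort_reproduces_requested_venn():
    counts = {"both": 35, "nhr23_only": 16, "let7_only": 7, "neither": 9}
    cohort, truth = gen_ccg_cohort_exact(counts, seed=6)
    venn = tabulate([classify(ev) for ev in cohort])
    assert (venn.both, venn.nhr23_only, venn.let7_only, venn.neither) == (35, 16, 7, 9)
    assert venn.total == 67


def test_noiseless_expression_dampens_exactly():
    series, windows, truth = gen_expression(
        dampening_fold=1.5, n_stages=3, baseline=0.0, noise_sd=0.0, seed=7
    )
    from moltclock.waveform import dampening, segment_stages, stage_metrics

    metrics = [stage_metrics(s, 8.0) for s in segment_stages(series, windows)]
    assert dampening(metrics).ratios == pytest.approx((1.5, 1.5))


def test_negative_noise_rejected():
    with pytest.raises(ValueError):
        gen_expression(noise_sd=-0.1)


def test_deterministic_cohort_wake_to_wake():
    tracks, truth = gen_actograms(
        n_animals=6, active_mean_h=8.0, lethargus_mean_h=2.0,
        active_sd_h=0.0, lethargus_sd_h=0.0, sample_interval_h=1.0, seed=8,
    )
    assert all(wake_to_wake(t) == 10.0 for t in tracks)
    assert all(rec["wake_to_wake_h"] == 10.0 for rec in truth)


def test_knockdown_modifier_doubles_lethargus():
    wt, wt_truth = gen_actograms(n_animals=30, genotype="wild_type", seed=9)
    kd, kd_truth = gen_actograms(n_animals=30, genotype="nhr23_knockdown", seed=9)
    wt_leth = np.mean([r["lethargus_h"] for r in wt_truth])
    kd_leth = np.mean([r["lethargus_h"] for r in kd_truth])
    assert kd_leth / wt_leth == pytest.approx(2.0, rel=0.2)


def test_qpcr_and_chip_fixtures_round_trip_noiselessly():
    assert relative_expression(gen_qpcr(0.5)) == pytest.approx(0.5)
    assert relative_expression(gen_qpcr(1.0)) == pytest.approx(1.0)
    tagged, untagged = gen_chip(4.0)
    assert chip_fold_enrichment(tagged, untagged) == pytest.approx(4.0)


def test_qpcr_estimator_unbiased_under_replicate_noise():
    estimates = [
        relative_expression(gen_qpcr(0.5, noise_sd=0.1, replicates=3, seed=s))
        for s in range(100)
    ]
    # mean of 100 seeds within Monte-Carlo error of the planted level
    assert np.mean(estimates) == pytest.approx(0.5, abs=3 * np.std(estimates) / 10)
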