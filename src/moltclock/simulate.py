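"""Synthetic data with known ground truth for every pipeline stage.

Each generator emulates one class of study input — random DNA with planted
regulatory elements, per-gene evidence cohorts, dampened oscillatory
expression series, qPCR/ChIP fixtures, and behavioral cohorts — and emits
the ground truth needed to score the downstream analysis without reference
to generator internals.

Defaults encode the study conditions: a wild-type wake-to-wake interval of
10.3 h (8.0 h active + 2.3 h lethargus), knockdown-like cohorts that enter
lethargus slightly later and stay lethargic twice as long, let-7-like
cohorts with all intervals shortened, expression pulses whose peaks drop
~1.5-fold per stage, and 2-h expression sampling over three molts (14 time
samples). A single root seed is fanned out into per-component child
streams so modules regenerate independently.
"""

from __future__ import annotations

import zlib
from typing import Optional, Sequence

import numpy as np

from .actogram import ActivityState, AnimalTrack
from .mirna_sites import CELEGANS_LET7
from .quantify import ChipMeasurement, QpcrMeasurement
from .sequence_scan import (
    RORE_FORWARD_WORDS,
    RORE_REVERSE_WORDS,
    SequenceRecord,
    reverse_complement,
)
from .target_classify import CcgEvidence, TargetCall, classify
from .waveform import ExpressionSeries, StageWindows

__all__ = [
    "child_rng",
    "gen_sequence",
    "gen_ccg_cohort",
    "gen_ccg_cohort_exact",
    "gen_expression",
    "gen_actograms",
    "gen_adult_fate_tracks",
    "gen_qpcr",
    "gen_chip",
    "WT_ACTIVE_H",
    "WT_LETHARGUS_H",
    "GENOTYPE_BEHAVIOR_MODIFIERS",
]

_BASES = np.array(list("ACGT"))

#: Wild-type behavioral defaults: 8.0 h active + 2.3 h lethargus gives the
#: 10.3 h wake-to-wake interval of control L4-to-adult cohorts.
WT_ACTIVE_H = 8.0
WT_LETHARGUS_H = 2.3
WT_ACTIVE_SD_H = 0.3
WT_LETHARGUS_SD_H = 0.25

#: Behavioral modifiers by genotype class: knockdown-like animals enter
#: lethargus a little later and remain lethargic twice as long (W-W ~13 h);
#: let-7-like animals shorten all intervals (W-W ~7.9 h).
GENOTYPE_BEHAVIOR_MODIFIERS = {
    "wild_type": {"active_scale": 1.0, "active_shift_h": 0.0, "lethargus_scale": 1.0},
    "nhr23_knockdown": {
        "active_scale": 1.0,
        "active_shift_h": 0.4,
        "lethargus_scale": 2.0,
    },
    "let7_mutant": {
        "active_scale": 0.77,
        "active_shift_h": 0.0,
        "lethargus_scale": 0.77,
    },
}


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-component generator derived from one root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(stream.encode())])
    )


# ---------------------------------------------------------------------------
# sequences


def gen_sequence(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    plant: Sequence[tuple[str, int]] = (),
    motif_free: bool = False,
    forbidden_words: Optional[Sequence[str]] = None,
    seq_id: str = "synthetic",
) -> tuple[SequenceRecord, dict]:
    """Random DNA at a target GC fraction, optionally motif-free, with
    words planted at stated 1-based positions.

    ``motif_free`` resamples any window spelling a forbidden word (by
    default the RORE consensus on either strand plus the perfect let-7
    seed complement) until none remain; planting happens afterwards and
    rejects overlapping positions.
    """
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    rng = child_rng(seed, f"sequence/{seq_id}")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chars = rng.choice(_BASES, size=length, p=probs)
    seq = "".join(chars)

    if motif_free:
        if forbidden_words is None:
            forbidden_words = list(RORE_FORWARD_WORDS + RORE_REVERSE_WORDS)
            perfect = reverse_complement(CELEGANS_LET7.seed)
            forbidden_words += [perfect, reverse_complement(perfect)]
        seq_list = list(seq)
        for _ in range(100 * max(1, length)):
            hit = _find_forbidden("".join(seq_list), forbidden_words)
            if hit is None:
                break
            i, k = hit
            seq_list[i : i + k] = rng.choice(_BASES, size=k, p=probs)
        else:  # pragma: no cover - resampling failed to converge
            raise RuntimeError("could not purge forbidden motifs")
        seq = "".join(seq_list)

    planted = []
    occupied: list[tuple[int, int]] = []
    seq_list = list(seq)
    for word, pos in plant:
        word = word.upper()
        if not 1 <= pos <= length - len(word) + 1:
            raise ValueError(f"plant position {pos} outside sequence")
        span = (pos, pos + len(word) - 1)
        for a, b in occupied:
            if span[0] <= b and a <= span[1]:
                raise ValueError(f"planted words overlap at position {pos}")
        occupied.append(span)
        seq_list[pos - 1 : pos - 1 + len(word)] = list(word)
        planted.append({"word": word, "start": pos, "end": span[1]})
    record = SequenceRecord(seq_id, "".join(seq_list))
    truth = {"planted": planted, "gc": gc, "length": length, "motif_free": motif_free}
    return record, truth


def _find_forbidden(seq: str, words: Sequence[str]) -> Optional[tuple[int, int]]:
    for w in words:
        i = seq.find(w)
        if i >= 0:
            return i, len(w)
    return None


# ---------------------------------------------------------------------------
# evidence cohorts

_FLAGS = ("chip_peak", "rore_enriched", "knockdown_reduced", "alg1_bound", "lcs_enriched")


def gen_ccg_cohort(
    n: int, probs: Optional[dict[str, float]] = None, seed: int = 0
) -> tuple[list[CcgEvidence], list[TargetCall]]:
    """Independent Bernoulli evidence flags per gene; the true call is
    computed from the classification rules and returned alongside."""
    if n < 1:
        raise ValueError("need at least one gene")
    probs = probs or {flag: 0.5 for flag in _FLAGS}
    rng = child_rng(seed, "ccg_cohort")
    cohort = []
    for i in range(n):
        flags = {flag: bool(rng.random() < probs.get(flag, 0.5)) for flag in _FLAGS}
        cohort.append(CcgEvidence(gene_id=f"ccg{i + 1:03d}", oscillatory=True, **flags))
    return cohort, [classify(ev) for ev in cohort]


# Flag patterns per planted class: NHR-23 call needs >=2 of 3 criteria,
# let-7 call needs both of its 2 criteria.
_NHR23_TRUE = [p for p in np.ndindex(2, 2, 2) if sum(p) >= 2]
_NHR23_FALSE = [p for p in np.ndindex(2, 2, 2) if sum(p) < 2]
_LET7_TRUE = [(1, 1)]
_LET7_FALSE = [(0, 0), (0, 1), (1, 0)]


def gen_ccg_cohort_exact(
    counts: dict[str, int], seed: int = 0
) -> tuple[list[CcgEvidence], list[TargetCall]]:
    """Cohort with exact planted category counts.

    Serves as a synthetic stand-in for published per-gene evidence tables
    whose annotations are not redistributable: flag patterns are sampled
    among those consistent with each planted class, then shuffled.
    """
    rng = child_rng(seed, "ccg_cohort_exact")
    patterns = {
        TargetCall.BOTH: (_NHR23_TRUE, _LET7_TRUE),
        TargetCall.NHR23_ONLY: (_NHR23_TRUE, _LET7_FALSE),
        TargetCall.LET7_ONLY: (_NHR23_FALSE, _LET7_TRUE),
        TargetCall.NEITHER: (_NHR23_FALSE, _LET7_FALSE),
    }
    planned: list[TargetCall] = []
    for call in TargetCall:
        planned.extend([call] * int(counts.get(call.value, 0)))
    rng.shuffle(planned)  # type: ignore[arg-type]
    cohort = []
    for i, call in enumerate(planned):
        nhr_opts, let_opts = patterns[call]
        nhr = nhr_opts[rng.integers(len(nhr_opts))]
        let = let_opts[rng.integers(len(let_opts))]
        cohort.append(
            CcgEvidence(
                gene_id=f"ccg{i + 1:03d}",
                oscillatory=True,
                chip_peak=bool(nhr[0]),
                rore_enriched=bool(nhr[1]),
                knockdown_reduced=bool(nhr[2]),
                alg1_bound=bool(let[0]),
                lcs_enriched=bool(let[1]),
            )
        )
    return cohort, list(planned)


# ---------------------------------------------------------------------------
# expression series


def _raised_cosine(t: np.ndarray, peak_t: float, width: float) -> np.ndarray:
    """Smooth compact pulse of unit height centered on peak_t."""
    x = (t - peak_t) / width
    out = np.where(np.abs(x) <= 0.5, 0.5 * (1 + np.cos(2 * np.pi * x)), 0.0)
    return out


def gen_expression(
    n_stages: int = 3,
    stage_duration_h: float = 8.0,
    lethargus_duration_h: float = 2.0,
    base_amplitude: float = 3.0,
    dampening_fold: float = 1.5,
    peak_phase_fraction: float = 0.4,
    baseline: float = 0.2,
    noise_sd: float = 0.0,
    sampling_interval_h: float = 2.0,
    amplitude_scale: float = 1.0,
    duration_scale: float = 1.0,
    extra_pulse: bool = False,
    extra_pulse_fraction: float = 0.8,
    post_molt_h: float = 6.0,
    gene: str = "nhr-23",
    genotype: str = "wild_type",
    seed: int = 0,
) -> tuple[ExpressionSeries, StageWindows, dict]:
    """Per-stage dampened raised-cosine expression pulses.

    Stage s peaks at ``peak_phase_fraction`` of the way through the stage
    with pulse height ``base_amplitude / dampening_fold**(s-1)`` (peaks
    decline by ``dampening_fold`` per stage). Lethargi close each stage;
    genotype modifiers rescale amplitude and stage durations. An optional
    extra pulse after the final molt emulates derepressed genotypes.
    """
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    rng = child_rng(seed, f"expression/{gene}/{genotype}")
    dur = stage_duration_h * duration_scale
    leth = lethargus_duration_h * duration_scale
    if leth >= dur:
        raise ValueError("lethargus must be shorter than the stage")

    # lethargus j (j = 0..n_stages) spans [j*dur, j*dur + leth); stage s
    # runs lethargus-end to lethargus-end.
    lethargi = tuple((j * dur, j * dur + leth) for j in range(n_stages + 1))
    total = n_stages * dur + leth + (post_molt_h if extra_pulse else 0.0)
    t = np.arange(0.0, total + 1e-9, sampling_interval_h)

    signal = np.full_like(t, baseline)
    peaks = []
    for s in range(1, n_stages + 1):
        start = lethargi[s - 1][1]
        peak_t = start + peak_phase_fraction * dur
        height = amplitude_scale * base_amplitude / dampening_fold ** (s - 1)
        signal = signal + height * _raised_cosine(t, peak_t, 0.9 * dur)
        peaks.append({"stage": f"stage_{s}", "peak_time_h": peak_t, "peak_value": baseline + height})
    extra_pulse_time = None
    if extra_pulse:
        extra_pulse_time = lethargi[-1][1] + 0.5 * dur
        height = extra_pulse_fraction * (
            amplitude_scale * base_amplitude / dampening_fold ** (n_stages - 1)
        )
        signal = signal + height * _raised_cosine(t, extra_pulse_time, 0.9 * dur)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    signal = np.clip(signal, 0.0, None)

    series = ExpressionSeries(
        gene=gene,
        genotype=genotype,
        time_h=tuple(t),
        value=tuple(signal),
        normalization="synthetic, arbitrary units",
    )
    windows = StageWindows(lethargi=lethargi)
    truth = {
        "peaks": peaks,
        "dampening_fold": dampening_fold,
        "baseline": baseline,
        "peak_phase_fraction": peak_phase_fraction,
        "stage_duration_h": dur,
        "extra_pulse_time_h": extra_pulse_time,
        "true_dampening_ratios": [dampening_fold] * (n_stages - 1),
    }
    return series, windows, truth


# ---------------------------------------------------------------------------
# behavioral cohorts


def _n_samples(duration_h: float, dt: float) -> int:
    """Discretize a duration to the sampling grid, rounding half up."""
    return max(1, int(np.floor(duration_h / dt + 0.5)))


def gen_actograms(
    n_animals: int = 15,
    genotype: str = "wild_type",
    active_mean_h: float = WT_ACTIVE_H,
    active_sd_h: float = WT_ACTIVE_SD_H,
    lethargus_mean_h: float = WT_LETHARGUS_H,
    lethargus_sd_h: float = WT_LETHARGUS_SD_H,
    sample_interval_h: float = 1.0,
    apply_genotype_modifiers: bool = True,
    seed: int = 0,
) -> tuple[list[AnimalTrack], list[dict]]:
    """Cohort of tracks covering one full molting cycle.

    Each track runs: emergence (short residual activity), first lethargus,
    the stage's active interval, the closing lethargus, reawakening — so
    two lethargus exits define the wake-to-wake interval. Durations are
    drawn from normal distributions, floored at one sampling interval, and
    discretized to the grid (round half up).
    """
    if n_animals < 1:
        raise ValueError("need at least one animal")
    if active_mean_h <= 0 or lethargus_mean_h <= 0:
        raise ValueError("interval means must be positive")
    mods = (
        GENOTYPE_BEHAVIOR_MODIFIERS.get(genotype, GENOTYPE_BEHAVIOR_MODIFIERS["wild_type"])
        if apply_genotype_modifiers
        else GENOTYPE_BEHAVIOR_MODIFIERS["wild_type"]
    )
    mu_active = active_mean_h * mods["active_scale"] + mods["active_shift_h"]
    mu_leth = lethargus_mean_h * mods["lethargus_scale"]
    rng = child_rng(seed, f"actogram/{genotype}")
    dt = sample_interval_h
    tracks, truths = [], []
    for i in range(n_animals):
        leth1 = max(dt, rng.normal(mu_leth, lethargus_sd_h))
        active = max(dt, rng.normal(mu_active, active_sd_h))
        leth2 = max(dt, rng.normal(mu_leth, lethargus_sd_h))
        n_l1 = _n_samples(leth1, dt)
        n_act = _n_samples(active, dt)
        n_l2 = _n_samples(leth2, dt)
        states = (
            [ActivityState.ACTIVE_HIGH]  # emergence sample
            + [ActivityState.LETHARGIC] * n_l1
            + [ActivityState.ACTIVE_HIGH] * n_act
            + [ActivityState.LETHARGIC] * n_l2
            + [ActivityState.ACTIVE_HIGH]  # reawakening sample
        )
        tracks.append(
            AnimalTrack(
                animal_id=f"{genotype}_{i + 1:02d}",
                genotype=genotype,
                states=tuple(states),
                sample_interval_h=dt,
            )
        )
        truths.append(
            {
                "animal_id": f"{genotype}_{i + 1:02d}",
                "active_h": n_act * dt,
                "lethargus_h": n_l2 * dt,
                "wake_to_wake_h": (n_act + n_l2) * dt,
            }
        )
    return tracks, truths


def gen_adult_fate_tracks(
    n_animals: int = 34,
    fate_probs: Optional[dict[str, float]] = None,
    sample_interval_h: float = 2.0,
    seed: int = 0,
) -> tuple[list[AnimalTrack], list[str]]:
    """Quiescent adults singled and tracked for ~12 h: each track starts
    with a quiescent bout, then plays out its sampled fate (supernumerary
    molt with ecdysis behaviors, transient quiescence with reactivation,
    or death without molt signs)."""
    fate_probs = fate_probs or {"supernumerary_molt": 0.97, "transient_quiescence": 0.02, "death_without_molt": 0.01}
    total = sum(fate_probs.values())
    if not np.isclose(total, 1.0):
        raise ValueError("fate probabilities must sum to 1")
    rng = child_rng(seed, "adult_fates")
    names = list(fate_probs)
    probs = np.array([fate_probs[n] for n in names])
    tracks, fates = [], []
    for i in range(n_animals):
        fate = str(rng.choice(names, p=probs))
        bout = int(rng.integers(2, 5))  # 4-8 h quiescent at 2-h sampling
        states = [ActivityState.LETHARGIC] * bout
        events: dict[str, int] = {}
        if fate == "supernumerary_molt":
            states += [ActivityState.ECDYSIS, ActivityState.ACTIVE_LOW]
            if rng.random() < 0.9:  # most animals die after the attempt
                events["death"] = len(states) - 1
        elif fate == "transient_quiescence":
            states += [ActivityState.ACTIVE_HIGH] * 3
        else:
            states += [ActivityState.LETHARGIC]
            events["death"] = len(states) - 1
        tracks.append(
            AnimalTrack(
                animal_id=f"adult_{i + 1:02d}",
                genotype="adult",
                states=tuple(states),
                sample_interval_h=sample_interval_h,
                events=events,
            )
        )
        fates.append(fate)
    return tracks, fates


# ---------------------------------------------------------------------------
# qPCR / ChIP fixtures


def gen_qpcr(
    true_relative: float,
    reference_ct: float = 20.0,
    replicates: int = 3,
    noise_sd: float = 0.0,
    sample_id: str = "sample",
    seed: int = 0,
) -> QpcrMeasurement:
    """Back-compute target Cts from a planted relative expression level
    (target Ct = reference Ct - log2(level)), with replicate noise."""
    if true_relative <= 0:
        raise ValueError("relative level must be positive")
    rng = child_rng(seed, f"qpcr/{sample_id}")
    target = reference_ct - np.log2(true_relative)
    t_reps = target + rng.normal(0, noise_sd, size=replicates)
    r_reps = reference_ct + rng.normal(0, noise_sd, size=replicates)
    return QpcrMeasurement(
        sample_id=sample_id,
        target_ct=tuple(np.clip(t_reps, 0, 45)),
        reference_ct=tuple(np.clip(r_reps, 0, 45)),
    )


def gen_chip(
    true_fold: float,
    untagged_recovery_ct: float = 6.0,
    input_ct: float = 20.0,
    n_per_strain: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[ChipMeasurement], list[ChipMeasurement]]:
    """Planted ChIP fold enrichment: tagged IP Cts sit log2(true_fold)
    cycles below untagged IP Cts after input normalization."""
    if true_fold <= 0:
        raise ValueError("fold enrichment must be positive")
    rng = child_rng(seed, "chip")
    untagged_ip = input_ct + untagged_recovery_ct
    tagged_ip = untagged_ip - np.log2(true_fold)
    tagged, untagged = [], []
    for i in range(n_per_strain):
        tagged.append(
            ChipMeasurement(
                f"tagged_{i + 1}", "tagged", tagged_ip + rng.normal(0, noise_sd), input_ct
            )
        )
        untagged.append(
            ChipMeasurement(
                f"untagged_{i + 1}", "untagged", untagged_ip + rng.normal(0, noise_sd), input_ct
            )
        )
    return tagged, untagged
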