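"""Actogram analytics: per-animal behavioral records around the molts.

Worms observed at fixed intervals (1 or 2 h) are scored as active (with a
pumping-rate grade) or lethargic; lethargus is the quiescent phase of each
molt during which neither pharyngeal pumping nor sinusoidal locomotion is
seen. From ordered per-animal state strings this module derives lethargus
bouts, active intervals, the wake-to-wake interval (the proxy for the
molting-cycle period), cohort summaries with delegated statistics, the
population fraction of quiescent adults, and the adult-fate rubric used to
call supernumerary molts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ActivityState",
    "AnimalTrack",
    "LethargusBout",
    "IntervalSummary",
    "AdultFate",
    "grade_activity",
    "lethargus_bouts",
    "wake_to_wake",
    "interval_summary",
    "cohort_summary",
    "fraction_quiescent",
    "classify_adult_fate",
]


class ActivityState(str, Enum):
    ACTIVE_HIGH = "active_high"
    ACTIVE_MEDIUM = "active_medium"
    ACTIVE_LOW = "active_low"
    LETHARGIC = "lethargic"
    ECDYSIS = "ecdysis"
    UNOBSERVED = "unobserved"

    @property
    def is_active(self) -> bool:
        return self in (
            ActivityState.ACTIVE_HIGH,
            ActivityState.ACTIVE_MEDIUM,
            ActivityState.ACTIVE_LOW,
        )


#: Event annotations recognized on tracks (first detection).
EVENT_KINDS = ("Mlt", "Rup", "death", "shed_cuticle", "aberrant_molt")


@dataclass(frozen=True)
class AnimalTrack:
    """Ordered behavior states of one animal at a fixed sampling interval.

    ``events`` maps annotation kind -> sample index of first detection.
    """

    animal_id: str
    genotype: str
    states: tuple[ActivityState, ...]
    sample_interval_h: float = 1.0
    t0: str = "emergence"
    events: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        states = tuple(ActivityState(s) for s in self.states)
        object.__setattr__(self, "states", states)
        if not states:
            raise ValueError(f"track {self.animal_id!r} has no states")
        if self.sample_interval_h <= 0:
            raise ValueError("sample_interval_h must be positive")
        for kind, idx in self.events.items():
            if kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {kind!r}")
            if not 0 <= idx < len(states):
                raise ValueError(f"event {kind!r} index {idx} outside track")


@dataclass(frozen=True)
class LethargusBout:
    onset: int  # first lethargic sample
    offset: int  # first subsequent non-lethargic sample (== onset+n)
    duration_h: float


@dataclass(frozen=True)
class IntervalSummary:
    active_interval_h: Optional[float]
    lethargus_interval_h: Optional[float]
    wake_to_wake_h: Optional[float]


class AdultFate(str, Enum):
    SUPERNUMERARY_MOLT = "supernumerary_molt"
    TRANSIENT_QUIESCENCE = "transient_quiescence"
    DEATH_WITHOUT_MOLT = "death_without_molt"


def grade_activity(
    pump_hz: float,
    wt_mean_hz: float,
    wt_sd_hz: float,
    locomotion_only: bool = False,
) -> str:
    """Grade activity on the one-way standard scale set by the wild-type
    pumping rate: high >= mean - 1 SD, medium in [mean - 2 SD, mean - 1 SD),
    low below mean - 2 SD. An animal with obvious sinusoidal locomotion but
    no captured pumps is scored active at a low level.
    """
    if wt_sd_hz <= 0:
        raise ValueError("wt_sd_hz must be positive")
    if pump_hz < 0:
        raise ValueError("pump rate cannot be negative")
    if locomotion_only:
        return "low"
    high_cut = wt_mean_hz - wt_sd_hz
    medium_cut = wt_mean_hz - 2 * wt_sd_hz
    if pump_hz >= high_cut:
        return "high"
    if pump_hz >= medium_cut:
        return "medium"
    return "low"


def lethargus_bouts(track: AnimalTrack) -> list[LethargusBout]:
    """Maximal runs of lethargic samples. Unobserved samples terminate a
    bout conservatively (with a warning), since the behavior in the gap is
    unknown."""
    bouts: list[LethargusBout] = []
    onset: Optional[int] = None
    saw_gap = False
    for i, state in enumerate(track.states):
        if state is ActivityState.LETHARGIC:
            if onset is None:
                onset = i
        else:
            if state is ActivityState.UNOBSERVED and onset is not None:
                saw_gap = True
            if onset is not None:
                bouts.append(
                    LethargusBout(onset, i, (i - onset) * track.sample_interval_h)
                )
                onset = None
    if onset is not None:
        bouts.append(
            LethargusBout(
                onset, len(track.states), (len(track.states) - onset) * track.sample_interval_h
            )
        )
    if saw_gap:
        warnings.warn(
            f"track {track.animal_id!r}: unobserved sample terminated a lethargus bout"
        )
    return bouts


def _lethargus_exits(track: AnimalTrack) -> list[int]:
    """Sample indices of transitions from lethargus to any observed
    non-lethargic state."""
    exits = []
    for bout in lethargus_bouts(track):
        if (
            bout.offset < len(track.states)
            and track.states[bout.offset] is not ActivityState.UNOBSERVED
        ):
            exits.append(bout.offset)
    return exits


def wake_to_wake(track: AnimalTrack) -> Optional[float]:
    """Hours between the first two sequential transitions from lethargus
    to activity; None (undefined) for tracks with fewer than two exits."""
    exits = _lethargus_exits(track)
    if len(exits) < 2:
        return None
    return (exits[1] - exits[0]) * track.sample_interval_h


def interval_summary(track: AnimalTrack) -> IntervalSummary:
    """Active, lethargus, and wake-to-wake intervals for one cycle.

    For a track with two lethargi, the active interval is the time between
    the first lethargus exit and the second lethargus onset, and
    wake-to-wake = active + lethargus at the sampling resolution.
    """
    bouts = lethargus_bouts(track)
    ww = wake_to_wake(track)
    active = None
    lethargus = None
    if len(bouts) >= 2:
        active = (bouts[1].onset - bouts[0].offset) * track.sample_interval_h
        lethargus = bouts[1].duration_h
    elif len(bouts) == 1:
        lethargus = bouts[0].duration_h
    return IntervalSummary(active, lethargus, ww)


def cohort_summary(
    tracks: Sequence[AnimalTrack],
    metric: str = "wake_to_wake_h",
    test: str = "anova",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genotype mean +/- SD of an interval metric, with delegated
    pairwise comparisons (Bonferroni-corrected t tests after one-way
    ANOVA, or Mann-Whitney U tests).

    Returns (summary table, pairwise-comparison table); the comparison
    table is empty for a single-genotype cohort.
    """
    rows = []
    for tr in tracks:
        value = getattr(interval_summary(tr), metric)
        if value is not None:
            rows.append((tr.genotype, tr.animal_id, value))
    if not rows:
        raise ValueError(f"metric {metric!r} undefined for every track")
    df = pd.DataFrame(rows, columns=["genotype", "animal_id", "value"])
    summary = (
        df.groupby("genotype")["value"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )
    groups = {g: sub["value"].to_numpy() for g, sub in df.groupby("genotype")}
    pairs = list(combinations(sorted(groups), 2))
    comp_rows = []
    n_tests = len(pairs)
    for a, b in pairs:
        if test == "mannwhitney":
            stat, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            name = "mannwhitney_u"
        else:
            stat, p = stats.ttest_ind(groups[a], groups[b])
            name = "t"
        comp_rows.append(
            (a, b, name, float(stat), float(p), min(1.0, float(p) * n_tests))
        )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["group_a", "group_b", "test", "statistic", "p_value", "p_bonferroni"],
    )
    return summary, comparisons


def fraction_quiescent(
    counts: pd.DataFrame, control: str = "wild_type"
) -> pd.DataFrame:
    """Quiescence prevalence per genotype and timepoint with a chi-square
    test against the age-matched control.

    ``counts`` needs columns: genotype, time_h, quiescent, total. Returns
    the same rows with ``fraction`` and ``p_chi2_vs_control`` (NaN for the
    control rows themselves).
    """
    required = {"genotype", "time_h", "quiescent", "total"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts must have columns {sorted(required)}")
    if (counts["total"] <= 0).any():
        raise ValueError("totals must be positive")
    if (counts["quiescent"] > counts["total"]).any():
        raise ValueError("quiescent count exceeds total")
    out = counts.copy()
    out["fraction"] = out["quiescent"] / out["total"]
    ctrl = counts[counts["genotype"] == control].set_index("time_h")
    pvals = []
    for _, row in out.iterrows():
        if row["genotype"] == control or row["time_h"] not in ctrl.index:
            pvals.append(math.nan)
            continue
        c = ctrl.loc[row["time_h"]]
        table = np.array(
            [
                [row["quiescent"], row["total"] - row["quiescent"]],
                [c["quiescent"], c["total"] - c["quiescent"]],
            ]
        )
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            pvals.append(1.0)  # identical degenerate margins
            continue
        _, p, _, _ = stats.chi2_contingency(table)
        pvals.append(float(p))
    out["p_chi2_vs_control"] = pvals
    return out


def classify_adult_fate(track: AnimalTrack) -> AdultFate:
    """Fate of a quiescent adult singled at the start of its bout.

    Supernumerary molt: after the initial quiescent bout the animal shows
    ecdysis behaviors, signs of an aberrant molt, or a shed cuticle is
    found. Death without any of those signs is death_without_molt.
    Otherwise the animal reactivated and was superficially normal at the
    endpoint: transient quiescence.
    """
    if track.states[0] is not ActivityState.LETHARGIC:
        raise ValueError(
            f"track {track.animal_id!r} does not start with a quiescent bout"
        )
    bout_end = 0
    while (
        bout_end < len(track.states)
        and track.states[bout_end] is ActivityState.LETHARGIC
    ):
        bout_end += 1
    molt_signs = any(
        s is ActivityState.ECDYSIS for s in track.states[bout_end:]
    ) or any(
        kind in track.events and track.events[kind] >= bout_end
        for kind in ("Mlt", "shed_cuticle", "aberrant_molt")
    )
    if molt_signs:
        return AdultFate.SUPERNUMERARY_MOLT
    if "death" in track.events:
        return AdultFate.DEATH_WITHOUT_MOLT
    return AdultFate.TRANSIENT_QUIESCENCE
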