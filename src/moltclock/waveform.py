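"""Oscillatory-expression waveform metrics for molting-clock genes.

Transcript levels of clock-controlled genes pulse once per larval stage.
Given a normalized expression time series and per-genotype lethargus
(molt) annotations, this module segments the series into stages, locates
the per-stage trough and peak, computes the rising slope, fits a
fixed-period harmonic (cosinor) to obtain amplitude and phase, quantifies
stage-over-stage dampening of peak values, flags extra post-adult pulses,
and compares genotypes after developmental time alignment.

The harmonic estimator replaces the MetaCycle package deliberately: with
the expected period fixed (8 h for L3, 10 h for L4 data) a linear
least-squares cosinor fit is fully determined, dependency-free, and easy
to validate; its amplitude is the fitted cosine amplitude (half the
peak-to-trough swing of a pure cosine).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionSeries",
    "StageWindows",
    "StageSeries",
    "WaveformMetrics",
    "DampeningProfile",
    "segment_stages",
    "peak_trough",
    "rising_slope",
    "harmonic_metrics",
    "stage_metrics",
    "dampening",
    "detect_extra_pulse",
    "align_and_compare",
]


@dataclass(frozen=True)
class ExpressionSeries:
    """A normalized expression time course for one gene and genotype."""

    gene: str
    genotype: str
    time_h: tuple[float, ...]
    value: tuple[float, ...]
    normalization: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_h", tuple(float(t) for t in self.time_h))
        object.__setattr__(self, "value", tuple(float(v) for v in self.value))
        if len(self.time_h) != len(self.value):
            raise ValueError("time and value lengths differ")
        if any(b <= a for a, b in zip(self.time_h, self.time_h[1:])):
            raise ValueError("time_h must be strictly increasing")
        if any(v < 0 for v in self.value):
            raise ValueError("expression values must be non-negative")


@dataclass(frozen=True)
class StageWindows:
    """Ordered, non-overlapping lethargus intervals for one genotype.

    Each larval stage spans from the end of one lethargus (emergence into
    the stage) to the end of the next (the molt that closes it); k
    annotated lethargi bound k-1 complete stages.
    """

    lethargi: tuple[tuple[float, float], ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        leth = tuple((float(a), float(b)) for a, b in self.lethargi)
        object.__setattr__(self, "lethargi", leth)
        for a, b in leth:
            if b <= a:
                raise ValueError(f"lethargus ({a}, {b}) has non-positive duration")
        for (_, b0), (a1, _) in zip(leth, leth[1:]):
            if a1 < b0:
                raise ValueError("lethargi must be ordered and non-overlapping")
        n_stages = max(0, len(leth) - 1)
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"stage_{i + 1}" for i in range(n_stages))
            )
        elif len(self.labels) != n_stages:
            raise ValueError("need one label per stage (len(lethargi) - 1)")

    def stage_spans(self) -> list[tuple[str, float, float]]:
        """(label, start_h, end_h) with start/end at lethargus ends."""
        return [
            (label, self.lethargi[i][1], self.lethargi[i + 1][1])
            for i, label in enumerate(self.labels)
        ]


@dataclass(frozen=True)
class StageSeries:
    """Samples attributed to one stage, including the preceding molt so
    that the trough before/during that molt is available."""

    label: str
    prev_lethargus: tuple[float, float]
    end_lethargus: tuple[float, float]
    time_h: tuple[float, ...]
    value: tuple[float, ...]

    @property
    def stage_start_h(self) -> float:
        return self.prev_lethargus[1]


@dataclass(frozen=True)
class WaveformMetrics:
    """Per-stage descriptors of one expression pulse."""

    stage: str
    trough_time_h: float
    trough_value: float
    peak_time_h: float
    peak_value: float
    rising_slope: float
    amplitude: float
    phase_h: float
    period_h: float


@dataclass(frozen=True)
class DampeningProfile:
    """Successive peak ratios peak_s / peak_{s+1}; ~1.5 per stage for
    nhr-23 in the wild type, ~1.0 when dampening is lost."""

    ratios: tuple[float, ...]


def segment_stages(
    series: ExpressionSeries, windows: StageWindows
) -> list[StageSeries]:
    """Attribute samples to stages.

    A stage's sub-series covers (previous lethargus start, stage-ending
    lethargus end], so the trough detected before or during the preceding
    molt is included. Stages without samples are skipped with a warning.
    """
    t = np.asarray(series.time_h)
    v = np.asarray(series.value)
    out: list[StageSeries] = []
    spans = windows.stage_spans()
    if not spans:
        raise ValueError("need at least two lethargi to bound a stage")
    for i, (label, _, _) in enumerate(spans):
        prev_leth = windows.lethargi[i]
        end_leth = windows.lethargi[i + 1]
        mask = (t > prev_leth[0]) & (t <= end_leth[1])
        if not mask.any():
            warnings.warn(f"stage {label!r} contains no samples; skipped")
            continue
        out.append(
            StageSeries(
                label=label,
                prev_lethargus=prev_leth,
                end_lethargus=end_leth,
                time_h=tuple(t[mask]),
                value=tuple(v[mask]),
            )
        )
    return out


def peak_trough(stage: StageSeries) -> tuple[tuple[float, float], tuple[float, float]]:
    """((trough_time, trough_value), (peak_time, peak_value)).

    The peak is the maximum sample within the stage span; the trough is
    the minimum over samples up to and including the peak (i.e. detected
    before or during the preceding molt or the rise). Ties break to the
    earliest time.
    """
    t = np.asarray(stage.time_h)
    v = np.asarray(stage.value)
    if len(t) < 3:
        raise ValueError(f"stage {stage.label!r}: need at least 3 samples")
    in_stage = t > stage.stage_start_h
    if not in_stage.any():
        in_stage = np.ones_like(t, dtype=bool)  # degenerate: no post-molt sample
    peak_idx = int(np.flatnonzero(in_stage)[np.argmax(v[in_stage])])
    rising = slice(0, peak_idx + 1)
    trough_idx = int(np.argmin(v[rising]))
    return (float(t[trough_idx]), float(v[trough_idx])), (
        float(t[peak_idx]),
        float(v[peak_idx]),
    )


def rising_slope(
    trough: tuple[float, float], peak: tuple[float, float]
) -> float:
    """Rate of ascent from trough to peak, in normalized units per hour."""
    (t0, v0), (t1, v1) = trough, peak
    if t1 == t0:
        if v1 == v0:
            return 0.0  # flat series: trough and peak coincide
        raise ValueError("peak and trough at the same time")
    if t1 < t0:
        raise ValueError("peak precedes trough")
    return (v1 - v0) / (t1 - t0)


def harmonic_metrics(
    time_h: Sequence[float], value: Sequence[float], period_h: float
) -> tuple[float, float]:
    """Fixed-period cosinor fit: value = m + A cos(2*pi*(t - phi)/T).

    Returns (A, phi) with A >= 0 and phi reduced to [0, T). Phase is in
    the same time frame as ``time_h`` (pass stage-relative times to get
    hours after stage start).
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(value, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 samples for a harmonic fit")
    w = 2 * np.pi / period_h
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("singular design: timepoints do not identify the harmonic")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    _, a, b = coef
    amplitude = float(np.hypot(a, b))
    phase = float(np.arctan2(b, a) / w) % period_h
    return amplitude, phase


def stage_metrics(stage: StageSeries, period_h: float) -> WaveformMetrics:
    """All waveform metrics for one stage (phase in hours after stage
    start)."""
    trough, peak = peak_trough(stage)
    t_rel = np.asarray(stage.time_h) - stage.stage_start_h
    amplitude, phase = harmonic_metrics(t_rel, stage.value, period_h)
    return WaveformMetrics(
        stage=stage.label,
        trough_time_h=trough[0],
        trough_value=trough[1],
        peak_time_h=peak[0],
        peak_value=peak[1],
        rising_slope=rising_slope(trough, peak),
        amplitude=amplitude,
        phase_h=phase,
        period_h=period_h,
    )


def dampening(metrics: Sequence[WaveformMetrics]) -> DampeningProfile:
    """Ordered successive peak ratios across stages."""
    if len(metrics) < 2:
        raise ValueError("need peaks from at least 2 stages")
    ratios = []
    for a, b in zip(metrics, metrics[1:]):
        if b.peak_value <= 0:
            raise ValueError(
                f"stage {b.stage!r} peak is non-positive; ratio undefined"
            )
        ratios.append(a.peak_value / b.peak_value)
    return DampeningProfile(tuple(ratios))


def _local_maxima(v: np.ndarray) -> np.ndarray:
    """Indices i with v[i] > v[i-1] (or i == 0) and v[i] >= v[i+1] (or last)."""
    idx = []
    for i in range(len(v)):
        left_ok = i == 0 or v[i] > v[i - 1]
        right_ok = i == len(v) - 1 or v[i] >= v[i + 1]
        if left_ok and right_ok:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def detect_extra_pulse(
    series: ExpressionSeries,
    final_molt_end_h: float,
    threshold_fraction: float = 0.5,
    last_larval_peak: Optional[float] = None,
) -> tuple[bool, Optional[float]]:
    """Detect a supernumerary expression pulse after the final molt.

    True when an interior local maximum after ``final_molt_end_h`` exceeds
    ``threshold_fraction`` times the last larval peak. Because expression
    dampens across stages, the reference is the final pre-molt pulse (the
    last local maximum at or before the molt end), not the global larval
    maximum; pass ``last_larval_peak`` to override. Returns
    (detected, pulse_time_h).
    """
    t = np.asarray(series.time_h)
    v = np.asarray(series.value)
    before = np.flatnonzero(t <= final_molt_end_h)
    after = np.flatnonzero(t > final_molt_end_h)
    if len(after) == 0:
        raise ValueError("no samples after the final molt; extra pulse undefined")
    if len(before) == 0:
        raise ValueError("no samples before the final molt; larval peak undefined")
    if last_larval_peak is None:
        maxima = _local_maxima(v[before])
        last_larval_peak = float(v[before][maxima[-1]]) if len(maxima) else float(v[before].max())
    threshold = threshold_fraction * last_larval_peak
    for idx in after:
        left_ok = idx == 0 or v[idx] > v[idx - 1]
        right_ok = idx == len(v) - 1 or v[idx] >= v[idx + 1]
        if left_ok and right_ok and v[idx] > threshold:
            return True, float(t[idx])
    return False, None


def align_and_compare(
    series_a: ExpressionSeries,
    series_b: ExpressionSeries,
    shift_h: float = 0.0,
    time_tol_h: float = 1e-6,
) -> tuple[pd.DataFrame, float]:
    """Fold differences b/a at matched timepoints after shifting series_a
    left by ``shift_h``, plus a delegated two-way (genotype + time) ANOVA
    p-value for the genotype effect.

    Aligning by developmental stage compensates for genotypes that develop
    at different rates (e.g. wild type shifted 4 h relative to a faster
    mutant).
    """
    ta = np.asarray(series_a.time_h) - shift_h
    tb = np.asarray(series_b.time_h)
    rows = []
    for i, t in enumerate(ta):
        j = np.flatnonzero(np.abs(tb - t) <= time_tol_h)
        if len(j):
            rows.append((float(t), series_a.value[i], series_b.value[int(j[0])]))
    if not rows:
        raise ValueError("no overlapping timepoints after shift")
    df = pd.DataFrame(rows, columns=["time_h", "value_a", "value_b"])
    with np.errstate(divide="ignore", invalid="ignore"):
        df["fold_b_over_a"] = df["value_b"] / df["value_a"]

    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    long = pd.concat(
        [
            pd.DataFrame(
                {"time_h": df.time_h, "value": df.value_a, "genotype": series_a.genotype}
            ),
            pd.DataFrame(
                {"time_h": df.time_h, "value": df.value_b, "genotype": series_b.genotype}
            ),
        ]
    )
    fit = ols("value ~ C(genotype) + C(time_h)", data=long).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    p_genotype = float(table.loc["C(genotype)", "PR(>F)"])
    return df, p_genotype
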