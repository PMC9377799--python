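"""qPCR, ChIP-qPCR, and ratiometric-reporter arithmetic.

Relative transcript abundance follows the delta-Ct convention with
amplification efficiency fixed at 2.0 (100%): 2**-(Ct_target - Ct_ref).
ChIP recovery is normalized to input per sample (2**(Ct_input - Ct_IP));
fold enrichment is the tagged-strain mean over the untagged-strain mean.
Ratiometric reporter readout fits background-corrected channel intensity
against exposure time through the origin and takes the slope ratio over the
linear range of the assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import fmean
from typing import Sequence

import numpy as np

__all__ = [
    "QpcrMeasurement",
    "ChipMeasurement",
    "RoiSeries",
    "relative_expression",
    "normalize_to_control_mean",
    "chip_fold_enrichment",
    "ratiometric_signal",
    "worm_ratiometric_signal",
]


def _check_replicates(cts: Sequence[float], label: str) -> float:
    """Mean Ct; warn when a technical replicate deviates more than 5%
    from the replicate mean."""
    if not cts:
        raise ValueError(f"no {label} Ct values")
    for ct in cts:
        if not 0 <= ct <= 45:
            raise ValueError(f"{label} Ct {ct} outside [0, 45]")
    mean = fmean(cts)
    if mean > 0 and any(abs(ct - mean) > 0.05 * mean for ct in cts):
        warnings.warn(
            f"{label} technical replicates deviate >5% from their mean", stacklevel=3
        )
    return mean


@dataclass(frozen=True)
class QpcrMeasurement:
    """One RT-qPCR sample: technical-replicate Cts for target and
    reference amplicons."""

    sample_id: str
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]
    condition: str = ""
    time_h: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_ct", tuple(self.target_ct))
        object.__setattr__(self, "reference_ct", tuple(self.reference_ct))


@dataclass(frozen=True)
class ChipMeasurement:
    """One ChIP-qPCR sample (IP and input Cts for one amplicon)."""

    sample_id: str
    strain: str  # {"tagged", "untagged"}
    ip_ct: float
    input_ct: float
    amplicon: str = ""

    def __post_init__(self) -> None:
        if self.strain not in ("tagged", "untagged"):
            raise ValueError(f"strain must be 'tagged' or 'untagged', got {self.strain!r}")

    @property
    def input_normalized_recovery(self) -> float:
        return 2.0 ** (self.input_ct - self.ip_ct)


@dataclass(frozen=True)
class RoiSeries:
    """Background-corrected mean intensity of one ROI over an exposure
    ladder (exposures strictly increasing, ms)."""

    roi_id: str
    exposures_ms: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exposures_ms", tuple(self.exposures_ms))
        object.__setattr__(self, "intensity", tuple(self.intensity))
        if len(self.exposures_ms) != len(self.intensity):
            raise ValueError("exposures and intensities must have equal length")
        if any(b <= a for a, b in zip(self.exposures_ms, self.exposures_ms[1:])):
            raise ValueError("exposures must be strictly increasing")


def relative_expression(measurement: QpcrMeasurement) -> float:
    """2**-(mean target Ct - mean reference Ct), assuming 100% efficiency."""
    if not measurement.reference_ct:
        raise ValueError(f"sample {measurement.sample_id!r} has no reference Cts")
    t = _check_replicates(measurement.target_ct, "target")
    r = _check_replicates(measurement.reference_ct, "reference")
    return 2.0 ** -(t - r)


def normalize_to_control_mean(
    series: Sequence[float], control_series: Sequence[float]
) -> list[float]:
    """Divide each value by the mean of the control series (e.g. the
    average of all mock-treated time samples)."""
    if not control_series:
        raise ValueError("empty control series")
    mean = fmean(control_series)
    if mean <= 0:
        raise ValueError(f"control mean must be positive, got {mean}")
    return [v / mean for v in series]


def chip_fold_enrichment(
    tagged: Sequence[ChipMeasurement], untagged: Sequence[ChipMeasurement]
) -> float:
    """Mean input-normalized recovery in the tagged strain divided by the
    mean in the untagged (no-tag control) strain."""
    if not tagged or not untagged:
        raise ValueError("each strain needs at least one measurement")
    mean_tagged = fmean(m.input_normalized_recovery for m in tagged)
    mean_untagged = fmean(m.input_normalized_recovery for m in untagged)
    return mean_tagged / mean_untagged


def _zero_intercept_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope through the origin and uncentered R^2."""
    slope = float(np.dot(x, y) / np.dot(x, x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, r2


def ratiometric_signal(
    red: RoiSeries, green: RoiSeries, linear_r2: float = 0.99
) -> float:
    """Red/green slope ratio over the linear range of the exposure ladder.

    The linear range is the longest prefix of exposures (>= 3 points) for
    which a zero-intercept fit attains R^2 >= ``linear_r2`` in both
    channels; saturated top exposures therefore drop out.
    """
    if red.exposures_ms != green.exposures_ms:
        raise ValueError("red and green ROI series must share the exposure ladder")
    n = len(red.exposures_ms)
    if n < 3:
        raise ValueError("need at least 3 exposures")
    x = np.asarray(red.exposures_ms, dtype=float)
    yr = np.asarray(red.intensity, dtype=float)
    yg = np.asarray(green.intensity, dtype=float)
    for stop in range(n, 2, -1):
        slope_r, r2_r = _zero_intercept_fit(x[:stop], yr[:stop])
        slope_g, r2_g = _zero_intercept_fit(x[:stop], yg[:stop])
        if r2_r >= linear_r2 and r2_g >= linear_r2:
            if slope_g == 0:
                raise ValueError("green channel slope is zero")
            return slope_r / slope_g
    raise ValueError(
        f"no linear prefix of >=3 exposures attains R^2 >= {linear_r2} in both channels"
    )


def worm_ratiometric_signal(
    rois: Sequence[tuple[RoiSeries, RoiSeries]], linear_r2: float = 0.99
) -> float:
    """Per-worm readout: mean of per-ROI red/green ratios (ratio first,
    then average over the worm's ROIs)."""
    if not rois:
        raise ValueError("need at least one ROI pair")
    return fmean(ratiometric_signal(r, g, linear_r2) for r, g in rois)
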