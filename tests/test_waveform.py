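"""Oscillatory-waveform metrics: segmentation, peaks, slopes, harmonic
fit, dampening, extra pulses, and genotype comparison."""

import math

import numpy as np
import pytest

from moltclock.simulate import gen_expression
from moltclock.waveform import (
    ExpressionSeries,
    StageSeries,
    StageWindows,
    WaveformMetrics,
    align_and_compare,
    dampening,
    detect_extra_pulse,
    harmonic_metrics,
    peak_trough,
    rising_slope,
    segment_stages,
    stage_metrics,
)


def _series(times, values, genotype="wild_type"):
    return ExpressionSeries("nhr-23", genotype, tuple(times), tuple(values))


def _stage(times, values, prev=(0.0, 2.0), end=(8.0, 10.0), label="stage_1"):
    return StageSeries(label, prev, end, tuple(times), tuple(values))


def test_fourteen_samples_three_lethargi_give_two_stages():
    times = [2 * i for i in range(14)]  # 0..26 h at 2-h spacing
    values = [1.0] * 14
    windows = StageWindows(lethargi=((0, 2), (12, 14), (24, 26)))
    stages = segment_stages(_series(times, values), windows)
    assert [s.label for s in stages] == ["stage_1", "stage_2"]
    # stage 1 covers (0, 14]: trough search reaches back into lethargus 0
    assert stages[0].time_h[0] == 2.0 and stages[0].time_h[-1] == 14.0


def test_series_inside_single_stage():
    windows = StageWindows(lethargi=((0, 2), (10, 12)))
    stages = segment_stages(_series([4, 6, 8], [1, 2, 1]), windows)
    assert len(stages) == 1 and stages[0].time_h == (4.0, 6.0, 8.0)


def test_empty_stage_is_skipped_with_warning():
    windows = StageWindows(lethargi=((0, 2), (10, 12), (20, 22)))
    with pytest.warns(UserWarning):
        stages = segment_stages(_series([4, 6, 8], [1, 2, 1]), windows)
    assert [s.label for s in stages] == ["stage_1"]


def test_segmentation_matches_generator_truth():
    series, windows, truth = gen_expression(n_stages=3, seed=4)
    stages = segment_stages(series, windows)
    assert len(stages) == 3
    for stage, peak in zip(stages, truth["peaks"]):
        assert stage.stage_start_h <= peak["peak_time_h"] <= stage.end_lethargus[1]


def test_peak_trough_example():
    stage = _stage([24, 30, 34], [0.5, 2.0, 1.0], prev=(22, 25), end=(32, 35))
    trough, peak = peak_trough(stage)
    assert trough == (24.0, 0.5) and peak == (30.0, 2.0)
    assert rising_slope(trough, peak) == pytest.approx(0.25)


def test_constant_series_has_flat_waveform():
    stage = _stage([2, 4, 6], [1.0, 1.0, 1.0])
    trough, peak = peak_trough(stage)
    assert trough[1] == peak[1]
    assert rising_slope(trough, peak) == 0.0


def test_peak_trough_matches_brute_force(rng):
    for _ in range(30):
        t = np.arange(0, 20, 2.0)
        v = rng.random(len(t))
        stage = _stage(t, v, prev=(-4, -2), end=(16, 18))
        trough, peak = peak_trough(stage)
        assert peak[1] == v.max() and peak[0] == t[np.argmax(v)]
        assert trough[1] == v[: np.argmax(v) + 1].min()


def test_rising_slope_errors_and_scaling():
    with pytest.raises(ValueError):
        rising_slope((5.0, 1.0), (5.0, 2.0))
    base = rising_slope((24.0, 0.5), (30.0, 2.0))
    scaled = rising_slope((24.0, 0.5 * 7), (30.0, 2.0 * 7))
    assert scaled == pytest.approx(7 * base)


def test_harmonic_recovers_noiseless_cosine():
    t = np.arange(0, 14, 2.0)
    y = 1.5 + 2.0 * np.cos(2 * np.pi * (t - 3.0) / 8.0)
    amp, phase = harmonic_metrics(t, y, 8.0)
    assert amp == pytest.approx(2.0, abs=1e-9)
    assert phase == pytest.approx(3.0, abs=1e-9)


def test_harmonic_on_constant_series_is_flat():
    t = np.arange(0, 14, 2.0)
    amp, _ = harmonic_metrics(t, np.full_like(t, 2.2), 8.0)
    assert amp == pytest.approx(0.0, abs=1e-9)


def test_harmonic_amplitude_scales_linearly():
    t = np.arange(0, 16, 2.0)
    y = 1.0 + np.cos(2 * np.pi * (t - 1.0) / 10.0)
    a1, _ = harmonic_metrics(t, y, 10.0)
    a2, _ = harmonic_metrics(t, 3.5 * y, 10.0)
    assert a2 == pytest.approx(3.5 * a1)


def test_harmonic_rejects_degenerate_design():
    with pytest.raises(ValueError):
        harmonic_metrics([1, 1, 1, 1], [0, 1, 2, 3], 8.0)


def _metrics(stage, peak_value):
    return WaveformMetrics(stage, 0, 0, 1, peak_value, 0, 0, 0, 8.0)


def test_dampening_ratios():
    profile = dampening([_metrics("L2", 3.0), _metrics("L3", 2.0), _metrics("L4", 4 / 3)])
    assert profile.ratios == pytest.approx((1.5, 1.5))
    flat = dampening([_metrics("L3", 2.0), _metrics("L4", 2.0)])
    assert flat.ratios == pytest.approx((1.0,))  # no detectable dampening
    with pytest.raises(ValueError):
        dampening([_metrics("L3", 1.0), _metrics("L4", 0.0)])


def test_monotone_decay_is_not_an_extra_pulse():
    series = _series([0, 2, 4, 6, 8, 10], [1.0, 2.0, 1.0, 0.6, 0.4, 0.2])
    detected, where = detect_extra_pulse(series, final_molt_end_h=4.0)
    assert detected is False and where is None


def test_planted_post_molt_pulse_is_detected_at_its_location():
    series, windows, truth = gen_expression(extra_pulse=True, seed=3)
    detected, where = detect_extra_pulse(series, windows.lethargi[-1][1])
    assert detected is True
    assert where == pytest.approx(truth["extra_pulse_time_h"], abs=2.0)


def test_weak_post_molt_bump_below_threshold_is_ignored():
    series, windows, _ = gen_expression(
        extra_pulse=True, extra_pulse_fraction=0.1, seed=3
    )
    assert detect_extra_pulse(series, windows.lethargi[-1][1])[0] is False


def test_extra_pulse_requires_post_molt_samples():
    with pytest.raises(ValueError):
        detect_extra_pulse(_series([0, 2, 4], [1, 2, 1]), final_molt_end_h=10.0)


def test_align_identical_series():
    a = _series([0, 2, 4, 6], [1, 2, 3, 2], genotype="wild_type")
    b = _series([0, 2, 4, 6], [1, 2, 3, 2], genotype="mutant")
    df, _ = align_and_compare(a, b, shift_h=0.0)
    assert df["fold_b_over_a"].tolist() == [1.0] * 4


def test_align_recovers_uniform_fold_after_shift():
    t = [4, 6, 8, 10]
    a = _series(t, [1.0, 2.0, 3.0, 2.0], genotype="wild_type")
    b = _series([x - 4 for x in t], [1.6, 3.2, 4.8, 3.2], genotype="mutant")
    df, p = align_and_compare(a, b, shift_h=4.0)
    assert df["fold_b_over_a"].tolist() == pytest.approx([1.6] * 4)
    assert 0 <= p <= 1


def test_metrics_invariant_to_time_translation():
    series, windows, _ = gen_expression(seed=8, baseline=0.0)
    shift = 13.0
    shifted = ExpressionSeries(
        series.gene, series.genotype, tuple(t + shift for t in series.time_h), series.value
    )
    shifted_windows = StageWindows(
        lethargi=tuple((a + shift, b + shift) for a, b in windows.lethargi)
    )
    base = [stage_metrics(s, 8.0) for s in segment_stages(series, windows)]
    moved = [stage_metrics(s, 8.0) for s in segment_stages(shifted, shifted_windows)]
    for m0, m1 in zip(base, moved):
        assert m1.peak_value == pytest.approx(m0.peak_value)
        assert m1.peak_time_h - m0.peak_time_h == pytest.approx(shift)
        assert m1.rising_slope == pytest.approx(m0.rising_slope)
        assert m1.amplitude == pytest.approx(m0.amplitude)
        assert m1.phase_h == pytest.approx(m0.phase_h)
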