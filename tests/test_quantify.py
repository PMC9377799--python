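"""qPCR, ChIP-qPCR, and ratiometric reporter arithmetic."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from moltclock.quantify import (
    ChipMeasurement,
    QpcrMeasurement,
    RoiSeries,
    chip_fold_enrichment,
    normalize_to_control_mean,
    ratiometric_signal,
    relative_expression,
    worm_ratiometric_signal,
)


def _qpcr(target, reference):
    return QpcrMeasurement("s", tuple(target), tuple(reference))


@pytest.mark.parametrize(
    "target,reference,expected",
    [
        ([21.0], [20.0], 0.5),
        ([20.0], [20.0], 1.0),
        ([20.0, 20.0, 21.0], [19.0], 2 ** -(61 / 3 - 19)),
    ],
)
def test_relative_expression(target, reference, expected):
    assert relative_expression(_qpcr(target, reference)) == pytest.approx(expected)


@given(st.floats(-3, 3), st.floats(15, 30), st.floats(15, 30))
def test_relative_expression_shift_equivariance(shift, t, r):
    """Adding the same cycle offset to target and reference leaves the
    ratio unchanged."""
    base = relative_expression(_qpcr([t], [r]))
    shifted = relative_expression(_qpcr([t + shift], [r + shift]))
    assert shifted == pytest.approx(base, rel=1e-9)


def test_discordant_replicates_warn():
    with pytest.warns(UserWarning):
        relative_expression(_qpcr([20.0, 25.0], [20.0]))


def test_missing_reference_errors():
    with pytest.raises(ValueError):
        relative_expression(_qpcr([20.0], []))


def test_normalize_to_control_mean():
    assert normalize_to_control_mean([1, 2, 3], [1, 2, 3]) == [0.5, 1.0, 1.5]
    assert normalize_to_control_mean([4, 8], [2, 2]) == [2.0, 4.0]
    assert normalize_to_control_mean([0.3, 0.7], [1.0, 1.0]) == [0.3, 0.7]
    with pytest.raises(ValueError):
        normalize_to_control_mean([1], [0.0, 0.0])


def _chip(strain, ip, inp):
    return ChipMeasurement("s", strain, ip, inp)


def test_chip_fold_enrichment():
    same = [_chip("tagged", 24, 20)], [_chip("untagged", 24, 20)]
    assert chip_fold_enrichment(*same) == pytest.approx(1.0)
    better = [_chip("tagged", 22, 20)], [_chip("untagged", 24, 20)]
    assert chip_fold_enrichment(*better) == pytest.approx(4.0)  # 2 cycles better
    example = [_chip("tagged", 24, 20)], [_chip("untagged", 26, 20)]
    assert chip_fold_enrichment(*example) == pytest.approx(2**-4 / 2**-6)


def test_chip_group_against_itself_is_one():
    group = [_chip("tagged", 23.5, 20), _chip("tagged", 24.5, 20)]
    mirror = [ChipMeasurement(m.sample_id, "untagged", m.ip_ct, m.input_ct) for m in group]
    assert chip_fold_enrichment(group, mirror) == pytest.approx(1.0)


def test_empty_strain_group_errors():
    with pytest.raises(ValueError):
        chip_fold_enrichment([], [_chip("untagged", 24, 20)])


def _roi(roi_id, exposures, intensity):
    return RoiSeries(roi_id, tuple(exposures), tuple(intensity))


def test_ratiometric_signal_slope_ratio():
    red = _roi("r", [10, 20, 30], [100, 200, 300])
    green = _roi("g", [10, 20, 30], [200, 400, 600])
    assert ratiometric_signal(red, green) == pytest.approx(0.5)
    assert ratiometric_signal(red, red) == pytest.approx(1.0)


def test_saturated_top_exposure_is_excluded():
    exposures = [10, 20, 30, 40]
    red = _roi("r", exposures, [100, 200, 300, 305])  # saturates at the top
    green = _roi("g", exposures, [200, 400, 600, 800])
    assert ratiometric_signal(red, green) == pytest.approx(0.5)


def test_ratiometric_gain_invariance():
    red = _roi("r", [10, 20, 30], [50, 100, 150])
    green = _roi("g", [10, 20, 30], [80, 160, 240])
    base = ratiometric_signal(red, green)
    gain = 3.7
    red2 = _roi("r", [10, 20, 30], [gain * v for v in red.intensity])
    green2 = _roi("g", [10, 20, 30], [gain * v for v in green.intensity])
    assert ratiometric_signal(red2, green2) == pytest.approx(base)


def test_no_linear_prefix_errors():
    red = _roi("r", [10, 20, 30], [100, 150, 120])
    green = _roi("g", [10, 20, 30], [200, 400, 600])
    with pytest.raises(ValueError):
        ratiometric_signal(red, green, linear_r2=0.999)


def test_worm_value_averages_roi_ratios():
    pairs = [
        (_roi("r1", [10, 20, 30], [100, 200, 300]), _roi("g1", [10, 20, 30], [200, 400, 600])),
        (_roi("r2", [10, 20, 30], [300, 600, 900]), _roi("g2", [10, 20, 30], [200, 400, 600])),
    ]
    assert worm_ratiometric_signal(pairs) == pytest.approx((0.5 + 1.5) / 2)
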