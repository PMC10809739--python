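"""Regional statistics and selection rules against brute-force oracles."""

import numpy as np
import pytest

from medfuse.fusion import (
    FusionConfig,
    WindowSpec,
    fuse_highpass,
    fuse_images,
    fuse_lowpass,
    fuse_pyramids,
    regional_mean,
    regional_variance,
)
from medfuse.transforms import TransformConfig, decompose

from conftest import random_image


# --- brute-force per-pixel oracles -------------------------------------------

def oracle_mean(arr, radius=1):
    p = np.pad(arr, radius, mode="symmetric")
    side = 2 * radius + 1
    out = np.empty_like(arr, dtype=float)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            out[i, j] = np.mean(p[i : i + side, j : j + side])
    return out


def oracle_var(arr, radius=1):
    p = np.pad(arr, radius, mode="symmetric")
    side = 2 * radius + 1
    out = np.empty_like(arr, dtype=float)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            win = p[i : i + side, j : j + side]
            out[i, j] = np.sum((win - np.mean(win)) ** 2) / side**2
    return out


# --- regional statistics ------------------------------------------------------

def test_regional_mean_of_constant_band():
    band = np.full((9, 9), 2.5)
    np.testing.assert_array_equal(regional_mean(band).values, 2.5)


def test_regional_mean_center_of_1_to_9_patch():
    patch = np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert regional_mean(patch).values[1, 1] == 5.0


def test_regional_variance_of_constant_band_is_zero():
    band = np.full((7, 7), -1.25)
    np.testing.assert_array_equal(regional_variance(band).values, 0.0)


def test_regional_variance_center_of_1_to_9_patch():
    # sum((x - 5)^2 for x in 1..9) / 9 = 60/9
    patch = np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert regional_variance(patch).values[1, 1] == pytest.approx(60.0 / 9.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_regional_stats_match_bruteforce_on_5x5(seed):
    arr = np.random.default_rng(seed).standard_normal((5, 5))
    np.testing.assert_allclose(regional_mean(arr).values, oracle_mean(arr), atol=1e-13)
    np.testing.assert_allclose(regional_variance(arr).values, oracle_var(arr), atol=1e-10)


def test_variance_map_is_nonnegative(rng):
    arr = rng.standard_normal((20, 20)) * 1e-6
    assert regional_variance(arr).values.min() >= 0.0


def test_window_spec_validation():
    with pytest.raises(ValueError):
        WindowSpec(radius=0)
    assert WindowSpec(radius=2).side == 5


# --- low-pass rule ------------------------------------------------------------

def test_lowpass_constant_inputs_select_brighter():
    x, y = np.full((8, 8), 10.0), np.full((8, 8), 4.0)
    np.testing.assert_array_equal(fuse_lowpass(x, y).values, 10.0)
    np.testing.assert_array_equal(fuse_lowpass(y, x).values, 10.0)


@pytest.mark.parametrize("tie", ["prefer_first", "average"])
def test_lowpass_identical_inputs_identity(tie):
    b = random_image(5, (12, 12))
    np.testing.assert_array_equal(fuse_lowpass(b, b, tie_break=tie).values, b)


@pytest.mark.parametrize("seed", range(10))
def test_lowpass_selection_matches_mean_oracle(seed):
    g = np.random.default_rng(seed)
    n = int(g.integers(8, 17))
    x, y = g.random((n, n)), g.random((n, n))
    fused = fuse_lowpass(x, y).values
    mask = oracle_mean(x) >= oracle_mean(y)
    np.testing.assert_array_equal(fused, np.where(mask, x, y))
    # every output coefficient comes from exactly one input
    assert np.all((fused == x) | (fused == y))


def test_lowpass_literal_comparison_uses_raw_coefficient():
    g = np.random.default_rng(99)
    x, y = g.random((10, 10)), g.random((10, 10))
    fused = fuse_lowpass(x, y, literal=True).values
    mask = x >= oracle_mean(y)
    np.testing.assert_array_equal(fused, np.where(mask, x, y))


# --- high-pass rule -----------------------------------------------------------

def test_highpass_zero_band_loses_to_step_edge():
    x = np.zeros((10, 10))
    y = np.zeros((10, 10))
    y[:, 5:] = 1.0
    fused = fuse_highpass(x, y).values
    active = oracle_var(y) > 0
    np.testing.assert_array_equal(fused[active], y[active])
    # exact variance ties (both zero) go to the first input
    np.testing.assert_array_equal(fused[~active], x[~active])


def test_highpass_identical_inputs_identity():
    b = random_image(6, (12, 12)) - 0.5
    np.testing.assert_array_equal(fuse_highpass(b, b).values, b)


@pytest.mark.parametrize("seed", range(10))
def test_highpass_selection_matches_variance_oracle(seed):
    g = np.random.default_rng(1000 + seed)
    n = int(g.integers(8, 17))
    x, y = g.standard_normal((n, n)), g.standard_normal((n, n))
    fused = fuse_highpass(x, y).values
    mask = oracle_var(x) >= oracle_var(y)
    np.testing.assert_array_equal(fused, np.where(mask, x, y))


def test_rule_shape_mismatch_raises():
    with pytest.raises(ValueError, match="mismatch"):
        fuse_lowpass(np.zeros((8, 8)), np.zeros((8, 9)))
    with pytest.raises(ValueError, match="mismatch"):
        fuse_highpass(np.zeros((8, 8)), np.zeros((9, 8)))


def test_average_tie_break_averages_exact_ties():
    x, y = np.full((6, 6), 1.0), np.full((6, 6), 3.0)
    fused = fuse_lowpass(x, y, tie_break="average")
    np.testing.assert_array_equal(fused.values, 3.0)
    fused_tie = fuse_lowpass(x, x + 0.0, tie_break="average")
    np.testing.assert_array_equal(fused_tie.values, 1.0)


# --- end-to-end pipeline ------------------------------------------------------

@pytest.mark.parametrize("backend", ["atrous", "nsct"])
def test_fuse_image_with_itself_is_identity(backend):
    img = random_image(21, (32, 32))
    cfg = FusionConfig(transform=TransformConfig(backend=backend))
    fused, report = fuse_images(img, img, cfg)
    assert np.abs(fused - img).max() <= 1e-6 * (img.max() - img.min())
    assert report.ssim_fused_x == pytest.approx(1.0, abs=1e-9)


def test_fuse_constant_images_selects_brighter():
    x, y = np.full((32, 32), 10.0), np.full((32, 32), 4.0)
    fused, _ = fuse_images(x, y)
    np.testing.assert_allclose(fused, 10.0, atol=1e-9)


def test_symmetry_up_to_ties():
    """Without exact regional-statistic ties the fusion is order-invariant."""
    a, b = random_image(31, (32, 32)), random_image(32, (32, 32))
    f_ab, _ = fuse_images(a, b)
    f_ba, _ = fuse_images(b, a)
    np.testing.assert_allclose(f_ab, f_ba, atol=1e-12)


def test_selection_property_in_every_subband():
    """Before reconstruction each fused coefficient is X's or Y's, exactly."""
    a, b = random_image(41, (32, 32)), random_image(42, (32, 32))
    cfg = FusionConfig()
    pa, pb = decompose(a, cfg.transform), decompose(b, cfg.transform)
    fused_pyr, _, _ = fuse_pyramids(pa, pb, cfg)
    assert np.all(
        (fused_pyr.lowpass.values == pa.lowpass.values)
        | (fused_pyr.lowpass.values == pb.lowpass.values)
    )
    for sf, sa, sb in zip(fused_pyr.scales, pa.scales, pb.scales):
        for bf, bx, by in zip(sf, sa, sb):
            assert np.all((bf.values == bx.values) | (bf.values == by.values))


def test_report_selection_fractions_are_fractions():
    a, b = random_image(51, (32, 32)), random_image(52, (32, 32))
    _, report = fuse_images(a, b)
    assert 0.0 <= report.lowpass_fraction_from_x <= 1.0
    for scale in report.highpass_fraction_from_x:
        for frac in scale:
            assert 0.0 <= frac <= 1.0
    assert [len(s) for s in report.highpass_fraction_from_x] == [3, 3, 3]


def test_fuse_images_shape_mismatch_names_shapes():
    with pytest.raises(ValueError, match=r"\(16, 16\).*\(16, 17\)"):
        fuse_images(np.zeros((16, 16)), np.zeros((16, 17)))


def test_fusion_config_rejects_unknown_tie_policy():
    with pytest.raises(ValueError, match="tie_break"):
        FusionConfig(tie_break="random")
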