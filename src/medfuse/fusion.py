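"""Regional-statistics selection rules and the end-to-end fusion pipeline.

The fused decomposition is assembled coefficient-by-coefficient from the
two source pyramids:

* low-pass band — at each position the coefficient whose *regional mean*
  (arithmetic mean over a small centred window, 3x3 by default) is larger
  wins; the regional mean is a local brightness measure, so this rule
  favours the modality that renders a structure at all.
* every directional high-pass band — the coefficient whose *regional
  variance* (population variance over the same window) is larger wins;
  variance is a local activity/saliency measure, so this rule keeps the
  sharper edge or texture of the two modalities.

Window statistics use symmetric-reflection borders (a window must not wrap
around the anatomy), while the transform itself is periodic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .metrics import SSIMParams, ssim
from .transforms import Band, CoefficientPyramid, TransformConfig, decompose, reconstruct

__all__ = [
    "WindowSpec",
    "FusionConfig",
    "RegionalStatMap",
    "FusionReport",
    "regional_mean",
    "regional_variance",
    "fuse_lowpass",
    "fuse_highpass",
    "fuse_pyramids",
    "fuse_images",
]

_TIE_POLICIES = ("prefer_first", "average")


@dataclass(frozen=True)
class WindowSpec:
    """Square window of side ``2*radius + 1`` with reflected borders."""

    radius: int = 1
    boundary: str = "symmetric"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("window radius must be >= 1")
        if self.boundary != "symmetric":
            raise ValueError("only symmetric-reflection borders are supported")

    @property
    def side(self) -> int:
        return 2 * self.radius + 1


@dataclass(frozen=True)
class FusionConfig:
    """Transform layout, window and tie policy for :func:`fuse_images`.

    ``literal_lowpass`` switches the low-pass rule to the asymmetric
    comparison of a raw coefficient of the first image against the second
    image's regional mean; the default compares regional mean against
    regional mean, which is symmetric in the two inputs.
    """

    transform: TransformConfig = field(default_factory=TransformConfig)
    window: WindowSpec = field(default_factory=WindowSpec)
    tie_break: str = "prefer_first"
    literal_lowpass: bool = False

    def __post_init__(self) -> None:
        if self.tie_break not in _TIE_POLICIES:
            raise ValueError(
                f"tie_break must be one of {_TIE_POLICIES}, got {self.tie_break!r}"
            )


@dataclass(frozen=True)
class RegionalStatMap:
    """Per-position window statistic of a band (same shape as the band)."""

    values: np.ndarray
    kind: str  # "mean" or "variance"


@dataclass
class FusionReport:
    """Diagnostics of one fusion run.

    ``highpass_fraction_from_x[k][d]`` is the fraction of coefficients of
    scale ``k`` (coarsest first), direction ``d`` that were selected from
    the first input; ties count toward the first input.
    """

    ssim_fused_x: float
    ssim_fused_y: float
    lowpass_fraction_from_x: float
    highpass_fraction_from_x: list[list[float]]
    config: FusionConfig


def _band_values(band) -> np.ndarray:
    arr = band.values if isinstance(band, Band) else np.asarray(band, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D band, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("band contains non-finite values")
    return arr


def _windowed(arr: np.ndarray, window: WindowSpec) -> np.ndarray:
    r = window.radius
    padded = np.pad(arr, r, mode="symmetric")
    return sliding_window_view(padded, (window.side, window.side))


def regional_mean(band, window: WindowSpec | None = None) -> RegionalStatMap:
    """Mean of the ``(2r+1)^2`` coefficients around each position."""
    window = window or WindowSpec()
    arr = _band_values(band)
    return RegionalStatMap(_windowed(arr, window).mean(axis=(-2, -1)), kind="mean")


def regional_variance(band, window: WindowSpec | None = None) -> RegionalStatMap:
    """Population variance (divide by window size) around each position."""
    window = window or WindowSpec()
    arr = _band_values(band)
    return RegionalStatMap(_windowed(arr, window).var(axis=(-2, -1)), kind="variance")


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"band shape mismatch: {x.shape} vs {y.shape}")


def _select(
    x: np.ndarray,
    y: np.ndarray,
    stat_x: np.ndarray,
    stat_y: np.ndarray,
    tie_break: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position winner-take-all selection; returns (fused, mask_from_x)."""
    take_x = stat_x >= stat_y
    if tie_break == "prefer_first":
        fused = np.where(take_x, x, y)
    else:  # average on exact ties
        tie = stat_x == stat_y
        fused = np.where(take_x, x, y)
        fused = np.where(tie, 0.5 * (x + y), fused)
    return fused, take_x


def fuse_lowpass(
    low_x,
    low_y,
    window: WindowSpec | None = None,
    tie_break: str = "prefer_first",
    literal: bool = False,
) -> Band:
    """Maximum-regional-mean selection for the approximation bands.

    With ``literal=True`` the first image's raw coefficient is compared
    against the second image's regional mean instead of mean-vs-mean.
    """
    window = window or WindowSpec()
    x, y = _band_values(low_x), _band_values(low_y)
    _check_shapes(x, y)
    if literal:
        stat_x, stat_y = x, regional_mean(y, window).values
    else:
        stat_x = regional_mean(x, window).values
        stat_y = regional_mean(y, window).values
    fused, _ = _select(x, y, stat_x, stat_y, tie_break)
    return Band(fused)


def fuse_highpass(
    hi_x,
    hi_y,
    window: WindowSpec | None = None,
    tie_break: str = "prefer_first",
) -> Band:
    """Maximum-regional-variance selection for a directional detail band."""
    window = window or WindowSpec()
    x, y = _band_values(hi_x), _band_values(hi_y)
    _check_shapes(x, y)
    stat_x = regional_variance(x, window).values
    stat_y = regional_variance(y, window).values
    fused, _ = _select(x, y, stat_x, stat_y, tie_break)
    return Band(fused)


def fuse_pyramids(
    pyr_x: CoefficientPyramid,
    pyr_y: CoefficientPyramid,
    config: FusionConfig,
) -> tuple[CoefficientPyramid, float, list[list[float]]]:
    """Apply both selection rules band-wise to two coefficient pyramids.

    Returns the fused pyramid together with the fraction of low-pass and
    per-band high-pass coefficients taken from the first pyramid.
    """
    window, tie = config.window, config.tie_break
    lx, ly = pyr_x.lowpass.values, pyr_y.lowpass.values
    _check_shapes(lx, ly)
    if config.literal_lowpass:
        stat_x, stat_y = lx, regional_mean(ly, window).values
    else:
        stat_x = regional_mean(lx, window).values
        stat_y = regional_mean(ly, window).values
    fused_low, low_mask = _select(lx, ly, stat_x, stat_y, tie)

    fused_scales: list[list[Band]] = []
    hi_fractions: list[list[float]] = []
    for bands_x, bands_y in zip(pyr_x.scales, pyr_y.scales, strict=True):
        fused_bands: list[Band] = []
        fractions: list[float] = []
        for bx, by in zip(bands_x, bands_y, strict=True):
            x, y = bx.values, by.values
            _check_shapes(x, y)
            sx = regional_variance(x, window).values
            sy = regional_variance(y, window).values
            fused, mask = _select(x, y, sx, sy, tie)
            fused_bands.append(Band(fused))
            fractions.append(float(mask.mean()))
        fused_scales.append(fused_bands)
        hi_fractions.append(fractions)

    fused_pyr = CoefficientPyramid(
        lowpass=Band(fused_low),
        scales=fused_scales,
        meta=dict(pyr_x.meta),
    )
    return fused_pyr, float(low_mask.mean()), hi_fractions


def fuse_images(
    image_x,
    image_y,
    config: FusionConfig | None = None,
) -> tuple[np.ndarray, FusionReport]:
    """Fuse two co-registered grayscale images.

    Both images are decomposed with the configured transform, the low-pass
    bands are merged by maximum regional mean, every directional band by
    maximum regional variance, and the fused pyramid is inverted back to
    an image.  The report carries SSIM of the fused image against each
    input (global statistics, dynamic range from the pooled inputs) and
    the per-band selection fractions.
    """
    if config is None:
        config = FusionConfig()
    x = np.asarray(image_x, dtype=float)
    y = np.asarray(image_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"image shape mismatch: {x.shape} vs {y.shape}")

    pyr_x = decompose(x, config.transform)
    pyr_y = decompose(y, config.transform)
    fused_pyr, low_frac, hi_fracs = fuse_pyramids(pyr_x, pyr_y, config)
    fused = reconstruct(fused_pyr, config.transform)

    pooled = np.concatenate([x.ravel(), y.ravel()])
    dyn = float(pooled.max() - pooled.min())
    params = SSIMParams(dynamic_range=dyn if dyn > 0 else 1.0)
    report = FusionReport(
        ssim_fused_x=ssim(fused, x, params),
        ssim_fused_y=ssim(fused, y, params),
        lowpass_fraction_from_x=low_frac,
        highpass_fraction_from_x=hi_fracs,
        config=config,
    )
    return fused, report
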