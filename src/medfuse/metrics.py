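"""Structural similarity (SSIM) with its luminance/contrast/structure split.

SSIM compares two images through three terms built from first- and
second-order statistics (population moments):

    T(A,B) = (2 mu_A mu_B + c1) / (mu_A^2 + mu_B^2 + c1)        luminance
    D(A,B) = (2 sg_A sg_B + c2) / (sg_A^2 + sg_B^2 + c2)        contrast
    J(A,B) = (sg_AB + c3) / (sg_A sg_B + c3)                    structure

    SSIM(A,B) = T * D * J

With c3 = c2 / 2 the product collapses to the familiar closed form

    SSIM = (2 mu_A mu_B + c1)(2 sg_AB + c2)
           / ((mu_A^2 + mu_B^2 + c1)(sg_A^2 + sg_B^2 + c2)).

The stabilizing constants are c1 = (k1 L)^2 and c2 = (k2 L)^2 with
k1 = 0.01, k2 = 0.03 and L the dynamic range (1.0 for images normalised
to [0, 1]).

By default the statistics are *global* (one set of moments over the whole
image, one scalar per term).  ``mode="windowed"`` instead computes the
terms from Gaussian-weighted local moments (11x11 window, sigma 1.5) and
averages the local SSIM map over the interior, the sliding-window mean
SSIM common in the image-quality literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SSIMParams", "SSIMBreakdown", "ssim", "ssim_components", "ssim_combined"]


@dataclass(frozen=True)
class SSIMParams:
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0
    mode: str = "global"
    window_sigma: float = 1.5
    window_truncate: float = 3.5  # radius 5 -> 11x11 window at sigma 1.5

    def __post_init__(self) -> None:
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")
        if self.mode not in ("global", "windowed"):
            raise ValueError(f"mode must be 'global' or 'windowed', got {self.mode!r}")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


@dataclass(frozen=True)
class SSIMBreakdown:
    """The three comparison terms, the composite, and the image moments.

    In windowed mode the terms and composite are means of the local maps
    (so ``composite`` is the mean of the local products, not the product
    of the means) and the moment fields hold global statistics for
    reference.
    """

    luminance: float
    contrast: float
    structure: float
    composite: float
    mu_a: float
    mu_b: float
    sigma_a: float
    sigma_b: float
    sigma_ab: float


def _as_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shape mismatch: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("images contain non-finite values")
    return a, b


def _terms(mu_a, mu_b, var_a, var_b, cov, params: SSIMParams):
    sg_a = np.sqrt(np.maximum(var_a, 0.0))
    sg_b = np.sqrt(np.maximum(var_b, 0.0))
    c1, c2, c3 = params.c1, params.c2, params.c3
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    con = (2 * sg_a * sg_b + c2) / (sg_a**2 + sg_b**2 + c2)
    stru = (cov + c3) / (sg_a * sg_b + c3)
    return lum, con, stru, sg_a, sg_b


def ssim_components(a, b, params: SSIMParams | None = None) -> SSIMBreakdown:
    """Luminance, contrast and structure terms plus the composite index."""
    params = params or SSIMParams()
    a, b = _as_pair(a, b)

    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()

    if params.mode == "global":
        lum, con, stru, sg_a, sg_b = _terms(mu_a, mu_b, var_a, var_b, cov, params)
        composite = lum * con * stru
    else:
        sig, tr = params.window_sigma, params.window_truncate
        smooth = lambda x: gaussian_filter(x, sig, truncate=tr, mode="reflect")
        m_a, m_b = smooth(a), smooth(b)
        v_a = smooth(a * a) - m_a**2
        v_b = smooth(b * b) - m_b**2
        c_ab = smooth(a * b) - m_a * m_b
        lum_map, con_map, stru_map, _, _ = _terms(m_a, m_b, v_a, v_b, c_ab, params)
        pad = int(tr * sig + 0.5)
        if a.shape[0] > 2 * pad and a.shape[1] > 2 * pad:
            interior = (slice(pad, a.shape[0] - pad), slice(pad, a.shape[1] - pad))
        else:
            interior = (slice(None), slice(None))
        lum = float(lum_map[interior].mean())
        con = float(con_map[interior].mean())
        stru = float(stru_map[interior].mean())
        composite = float((lum_map * con_map * stru_map)[interior].mean())
        sg_a, sg_b = np.sqrt(var_a), np.sqrt(var_b)

    return SSIMBreakdown(
        luminance=float(lum),
        contrast=float(con),
        structure=float(stru),
        composite=float(composite),
        mu_a=float(mu_a),
        mu_b=float(mu_b),
        sigma_a=float(sg_a),
        sigma_b=float(sg_b),
        sigma_ab=float(cov),
    )


def ssim(a, b, params: SSIMParams | None = None) -> float:
    """Composite SSIM in [-1, 1]; 1 exactly when the images are identical."""
    return ssim_components(a, b, params).composite


def ssim_combined(a, b, params: SSIMParams | None = None) -> float:
    """The collapsed closed form; equals the T*D*J product when c3 = c2/2.

    Global statistics only — used as an internal consistency check of the
    product form.
    """
    params = params or SSIMParams()
    a, b = _as_pair(a, b)
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    c1, c2 = params.c1, params.c2
    return float(
        (2 * mu_a * mu_b + c1)
        * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )
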