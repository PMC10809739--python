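# Methods

## Decomposition backends

Both backends are *additive frames*: every band keeps the source
resolution and the source image equals the low-pass band plus the sum of
all directional bands. This makes reconstruction a plain sum, so perfect
reconstruction holds to machine precision by construction, and it makes
the two selection rules backend-agnostic — they only ever compare two
same-shaped bands.

**À-trous wavelet (default).** The pyramid low-pass is the separable
B3-spline kernel `[1, 4, 6, 4, 1]/16`, dilated with holes (tap spacing
`2^(k-1)` at scale `k`) and applied as a circular convolution. Per scale
the residual is split by the exact operator identity
`I = LxLy + (I−Lx)Ly + Lx(I−Ly) + (I−Lx)(I−Ly)` into horizontal, vertical
and diagonal detail bands (`Lx`/`Ly` the low-pass along columns/rows).
The "horizontal" band is high-pass along the horizontal axis and therefore
responds to vertical edges; a 32×32 vertical step puts all scale-1 detail
energy there and none in the diagonal band, which the tests verify against
a direct convolution oracle.

**Nonsubsampled contourlet-style (`nsct`).** The same à-trous pyramid
supplies a zero-DC high-pass residual per scale (the B3 kernel has unit DC
gain, so the residual's mean is exactly zero). A nonsubsampled directional
filter bank splits each residual into `2^d` oriented subbands. The
directional filters are implemented in the frequency domain as smooth
fan/wedge windows: raised-cosine functions of orientation (taken modulo π,
so each filter is Hermitian-symmetric and real in space) whose half-
overlapping supports form an exact partition of unity on `[0, π)`. The
design was genuinely open — spatial quincunx fan-filter ladders are the
historical construction — and the frequency-domain form was chosen because
it delivers the three contracted properties (perfect reconstruction, exact
shift equivariance, linearity) identically to round-off, with the filter
ids recorded in the pyramid metadata. Default layout: depth 3 with
direction exponents `(2, 3, 3)` coarsest-first, i.e. 4 directions at the
coarsest scale and 8 at the finer two — coarse scales resolve fewer
orientations reliably.

**Boundary handling.** Periodic (circular) inside the transform, which is
what makes shift equivariance exact and testable. Window statistics in the
fusion rules instead use symmetric reflection: a saliency window must not
wrap around the anatomy to the opposite border.

**Sizing.** An image must be at least `2^depth` pixels per axis; smaller
inputs raise an error naming the minimum. At depth 3 the dilated kernel
reaches ±8 pixels, so on very small images the circular taps wrap — legal,
but depth should be reduced for thumbnails.

## Fusion rules

Regional statistics use a centred square window of side `2r+1` (default
3×3) and population normalisation (divide by the window size, not `n−1`).
The low-pass rule compares regional means and keeps the coefficient of the
locally brighter modality; the high-pass rule compares regional variances
and keeps the locally more active coefficient. Selection is winner-take-
all, so before reconstruction every fused coefficient is bit-identical to
one of the two inputs — a property the tests assert subband by subband.

Choices made where the definitions were open:

- **Ties** (`stat_x == stat_y`) go to the first input by default
  (`prefer_first`, deterministic); an `average` policy that blends exact
  ties is available. Ties are measure-zero on real data but constant
  regions hit them systematically, so the policy is explicit.
- **Asymmetric low-pass variant.** `literal_lowpass=True` compares the
  first image's *raw* coefficient against the second image's regional
  mean. The default compares mean against mean, which is symmetric in the
  inputs and is what "take the larger regional mean" implies; the
  asymmetric variant is kept for comparability and is off by default.
- The window's index convention is the centred one (offsets `−r..+r`,
  `(2r+1)²` terms, divide by `(2r+1)²`).

## SSIM

Global statistics by default: one mean/variance/covariance per image,
matching the single-formula definition; `mode="windowed"` computes the
Gaussian-weighted sliding version (11×11 window, σ = 1.5, border-cropped
mean), which is cross-checked against scikit-image's implementation in the
tests. The contrast term carries the stabilising constant in **both**
numerator and denominator, `D = (2σ_Aσ_B + c₂)/(σ_A² + σ_B² + c₂)`; with
`c₃ = c₂/2` the product `T·D·J` then collapses algebraically to the
single-fraction closed form, and the tests require the two routes to agree
within 1e-12. Constants `k₁ = 0.01`, `k₂ = 0.03` with `L` the dynamic
range (1.0 for normalised images) follow the universal SSIM convention.
`fuse_images` infers `L` from the pooled input range.

## Phantom generator

The generator emulates the *complementarity* of multimodal pairs, not
their physics. A shared elliptical body (semi-axes 0.42/0.44 of the frame)
on a dark background carries three groups of axis-aligned ellipses and
rectangles: A-only (default 4), B-only (4) and shared (2). A-only
structures are rendered at body intensity in modality B — present in the
anatomy, invisible to that modality — and vice versa; the reference
renders all structures and is the target a perfect fusion would recover.
Default rendering: background 0.05, body 0.35, structure intensities drawn
uniformly from [0.70, 0.95]; each modality is blurred (Gaussian, σ = 1 px)
and corrupted with additive Gaussian noise (sd 0.02 of the dynamic range),
then clipped to [0, 1]; the reference is blur-matched but noise-free, so
SSIM against it measures structure recovery rather than deconvolution.
Intensity, noise and blur defaults are set to a regime typical of
normalised clinical slices: structures well above the body level, and
noise small relative to the structure-to-body contrast (~2% vs ~35–60% of
range), so modality differences are dominated by *missing structures*
rather than by noise.

Randomness is split into five fixed substreams (A geometry, shared
geometry, B geometry, A noise, B noise) via `SeedSequence.spawn`, and
structures are placed in that order with bounded rejection sampling
(non-overlapping, fully inside the body, 200 attempts before a placement
error). Consequently modality A is bit-identical across phantoms that
differ only in the B-only structure count — tested.

What passing the phantom suite does *not* show about clinical data: no
mis-registration, no modality-specific physics (beam hardening, bias
fields, speckle), no anatomical texture, axis-aligned analytic shapes
only. The fusion-gain result (fused SSIM ≥ best single modality − 0.01
over ten seeds) demonstrates the rules exploit complementarity; it is not
a clinical performance claim.

## Clinical worked-example fixtures

The published evaluation of this fusion approach exists only as printed
summary numbers; the package embeds them verbatim and recomputes every
derived statistic (concordance = diagonal/total, arithmetic means, gaps,
totals) at call time. The staging table is internally inconsistent — its
printed row totals (23, 41, 36) differ from the cell sums (18, 49, 33),
and the printed 69.5% overall accuracy differs from the recomputed 68% —
and `consistency_check` surfaces exactly those four records rather than
correcting the data. The printed per-phase accuracies (69.6/69.5/69.4%)
have no derivation from the table at all; they are carried in the report
as printed values only, with no recomputed counterpart. The printed
per-group t/p statistics are excluded: they cannot be reproduced from the
published fractions under any standard test.

## Problem sizes and numerical notes

The test and acceptance runs use 24–96 px images for property checks,
256×256 phantoms (10–13 seeds) for the fusion-gain sweep, and 20 seeded
instances for each oracle-equivalence sweep — sizes at which every
contract is already exercised at full tightness while the whole suite
runs in seconds. Regional statistics are computed with vectorised sliding
windows whose summation order differs from a per-pixel loop by ≤ 1 ulp;
oracle tests therefore compare statistics at 1e-13 (means) / 1e-10
(variances) and selection *masks* exactly. Variance maps are clipped at
zero against negative round-off. Reconstruction error is at machine
precision (~1e-15 of the dynamic range) for both backends, far inside the
1e-6 contract. All randomness in tests and scripts flows from explicit
integer seeds; `scripts/acceptance.py` derives every stream from its
`--seed` argument.
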