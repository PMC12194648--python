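# Methods

## The OCC representation

The model treats decolorization as a question about retinal activity rather
than luminance. The retina splits a trichromatic signal into parallel ON and
OFF pathways; the package idealizes this as two complementary channel banks.
The ON bank takes the stored sRGB channels literally — `L = R`, `M = G`,
`S = B` — plus a combined channel `LM = min(L + M, 1)`; the OFF bank is the
channel-wise complement (`-X = 1 − X`, `-LM = 1 − LM`). Activity and
inactivity are the bank means, so `A_on + A_off ≡ 1` is an algebraic
identity, not an approximation (tested to 1e-12 over random colours).

Two deliberate simplifications:

* **No cone-fundamental transform.** The literal channel mapping is what
  makes the worked values (yellow 3/4, blue 1/4) hold exactly; applying an
  LMS transform would be a different model.
* **No gamma linearization.** Channels are used as stored after exact
  division by 255. The representation is defined on nominal channel values;
  treating them as linear light would change every activity value.

Opponency and complementarity are distinct relations here: the *complement*
of a colour is its channel-wise inverse (the pair sums to white); the
*opponent* is the antipode on the OCC sphere, with activity `1 − A_on`. Only
the opponent's activity is computed — the general inverse mapping from
sphere coordinates back to a full channel vector is under-determined, so no
opponent channel reconstruction is attempted.

The sphere layout used for visualisation puts activity on the vertical axis
and hue on the azimuth with the four primaries equally spaced (red 0°,
yellow 90°, green 180°, blue 270°; hues between adjacent primaries
interpolate linearly, so cyan is 225° and magenta 315°). The radius is the
channel spread `max − min`, a visualisation-only convention — no computed
quantity depends on it. Achromatic colours report azimuth 0.

## Warm/cool dominance

`D = L − min(M + S, 1)` scores long-wavelength dominance in `[−1, 1]`;
`D ≥ 0` is warm. Two boundary facts worth knowing:

* Yellow and white land exactly on `D = 0` and are classified warm by the
  `≥` convention.
* The `min` saturation breaks the naive antisymmetry between complements:
  `D(red) = −D(cyan) = 1`, but `D(magenta) = 1 − min(0 + 1, 1) = 0`, not
  `−D(green) = 1`.

## The DWCA operator

The initial gray value of a pixel is its activity `A = A_on`. A logistic
adjustment then shifts warm pixels up and cool pixels down:

    A' = A + a (σ(kD) − 1/2),  a = W if D ≥ 0 else C
    G  = A' + s (σ(k(M−S)) − 1/2)   if D < 0, else A'

| parameter | meaning | range | default |
|---|---|---|---|
| `W` | warm brightening strength | ≥ 0 | 0.4 |
| `C` | cool darkening strength | ≥ 0 | 0.4 |
| `s` | cool M-over-S refinement | [0, 0.5], warn > 0.3 | 0.3 |
| `k` | sigmoid steepness | > 0 | 3 |

The sigmoid ensures that small dominance values — where the warm/cool
distinction matters most — still move the gray value; `k` controls how
quickly the shift saturates. Both strengths are entered non-negative: cool
pixels darken because `σ(kD) − 1/2` is negative when `D < 0`. The `s` term
separates greens from blues within the cool range; above 0.3 it starts to
push greens back toward their raw activity while crushing blues, hence the
warning. White and black are exact fixed points for every parameter setting
because `D = 0` and `M − S = 0` cancel the adjustment and `A` is already at
the boundary.

**Clamping.** Nothing bounds `A'`: saturated blue at the defaults reaches
−0.067, and large `W` can exceed 1. The final gray clamps to `[0, 1]` (a
displayable level) and the clamp is recorded per pixel; the CLI logs the
clamp count per image. Rescaling or tone-mapping instead of clamping would
make the gray level of a colour depend on the rest of the image, which the
per-pixel design forbids.

**Quantization.** 8-bit output rounds `255·G` half away from zero
(0.5 → 128), so threshold comparisons on quantized output are bit-exact and
reproducible. Metrics can be computed on either the float or the quantized
gray; tests pin the float path.

## Baselines

BT.601 is the standard ITU luma weighting (0.299, 0.587, 0.114). PCA
decolorization mean-centres the pixel cloud, projects it on the dominant
eigenvector of the per-image 3×3 colour covariance, orients the axis so it
correlates non-negatively with BT.601 luma (otherwise polarity would be
arbitrary per image), and min-max rescales to `[0, 1]`. A constant-colour
image has no principal axis and raises a degenerate-input error pointing at
BT.601. Third-party converters (contrast-analysis methods) are not
reimplemented; they plug into the method registry as adapters.

## Contrast metrics

For pixel pairs `(x, y)` with colour difference `‖x − y‖` and gray
difference `|g_x − g_y|`:

* `CCPR = |{pairs ∈ Ω : |g_x − g_y| ≥ τ}| / |Ω|` where Ω are sampled pairs
  with colour difference ≥ τ;
* `CCFR = 1 − |{pairs ∈ Θ : ‖x − y‖ ≤ τ}| / |Θ|` where Θ are sampled pairs
  with gray difference > τ;
* `E-score` = harmonic mean of the two (defined 0 at (0,0)).

**Units.** The colour distance is CIE76 ΔE in CIELAB (sRGB, D65); the gray
distance is the difference of CIELAB L* of the achromatic gray. Both then
share one perceptual-lightness scale on which τ = 4 is conventionally the
threshold of discernible contrast (τ ∈ {4, 10, 20} is the reported grid).
A `units="byte"` flag switches to 0-255 RGB-Euclidean/gray-level scales.

**Sampling.** 80 unordered pixel pairs drawn uniformly without replacement
(seeded); Ω and Θ are subsets of the same sample, so the CCPR denominator is
the realised `|Ω|`. When a requested sample exceeds the number of distinct
pairs the metric falls back to exhaustive enumeration with a notice. Empty
Ω or Θ yields 1.0 vacuously (logged) so dataset averages stay defined on
low-contrast images. On small images the exhaustive path is tested equal to
an independent double-loop enumeration, and the 80-pair estimate is tested
to converge to the exhaustive value within three standard errors over 200
seeds.

Note one subtlety: CCPR is *not* globally monotone in τ, because raising τ
both tightens the gray test and restricts Ω to high-ΔE pairs that may
survive better. The monotonicity that does hold — fixed pair set, increasing
gray threshold — is what the tests assert, via a `tau_gray` override.

**Composite C2G-SSIM.** The score is the windowed mean of
`L^α · C^β · S^γ` between the colour image's CIELAB lightness (scaled to
[0, 1]) and the gray image, with SSIM-style luminance/contrast/structure
terms (uniform window, default 11 px, standard SSIM regularizers for unit
range; structure clipped at 0 before exponentiation so fractional exponents
stay real). The component equations are documented stand-ins —
*composite-compatible*, not the original C2G-SSIM components — and no
acceptance check depends on this metric. It is 1 exactly when the gray
reproduces the reference lightness, and 1 trivially when α = β = γ = 0.

## Synthetic evaluation imagery

The plate generator reproduces the operative property of a
pseudoisochromatic plate rather than any copyrighted design: a disc of
non-overlapping dots in which dots under a digit-shaped glyph take warm
palette colours and the rest cool ones, with every palette entry projected
to one BT.601 luminance (default 0.5) by pure channel scaling — which
preserves hue and warm/cool category exactly. A luminance conversion
therefore separates figure from ground by ~0 while DWCA separates them by
≈ 0.2 gray levels at the defaults.

Construction details: greedy dart-throwing packs discs (radii 3-7 px,
uniform) with a 1 px gap until a 0.40 area-coverage target — chosen because
greedy random packing of this radius spread saturates near 0.42, so 0.40 is
reliably reached without a best-effort fallback — or a failure budget is
hit; dots are classified figure/ground by dot-centre membership in the
rasterized 5×7 bitmap glyph (embedded font, digits 0-9, scaled to ~60% of
the plate). Everything is driven by one seed; plates are bit-identical
across runs. Default plate size is 128-160 px in tests — large enough for
~100+ dots per plate and a stable figure/ground mean, small enough that the
20-plate evaluation runs in seconds.

Detection is the *separability* statistic: the absolute difference of mean
gray between figure-dot and ground-dot pixels, detected when ≥ 4/255 (the
τ = 4 convention rescaled to unit gray). This replaces human "seen/not-seen"
judgments with a continuous, reproducible proxy; it does not model glyph
legibility (shape recognition), only figure/ground contrast.

What the synthetic plates do *not* emulate: dot-size coding of secondary
figures, protan/deutan-specific confusion lines, vanishing and hidden-digit
designs, or print artefacts of clinical plates. Passing the confusion
property shows the conversions' behaviour on isoluminant warm/cool
figure-ground structure — the mechanism the clinical test exercises — not
clinical equivalence.

The warm/cool card is the analogous two-region fixture (warm disc, cool
disc, neutral ground, luma-matched by default) used for parameter-direction
sweeps; the colour chart covers the primaries/secondaries plus the gray
axis.

## Numerical conventions

* 8-bit inputs divide by 255 exactly; 16-bit inputs down-convert with a
  warning; alpha is dropped.
* `D = 0` classifies warm (the `≥` convention); this matters for yellow and
  the whole gray axis... except that grays have `D = −v` for level `v > 0`,
  so only black and white sit exactly on the boundary among achromatics.
* Complement involution is exact up to one ulp (`1 − (1 − x)` rounds for
  some doubles).
* Pair sampling, plate packing and benchmark seeds all derive from one
  user-supplied seed; image *i* in a benchmark uses `seed + i`.
* The benchmark driver shrinks the SSIM window to the largest odd size that
  fits when an image is smaller than the window, with a notice.

## Known limitations

* The literal RGB-to-cone mapping and missing gamma handling mean the model
  is a perceptual-coding idealization, not a colorimetric one; activities
  are not luminances.
* `W`, `C`, `s` are manual; no automatic per-image selection is provided.
* The composite C2G-SSIM is not comparable in absolute value to published
  scores computed with the original component equations.
* Benchmarks here run on synthetic fixtures; scores on external photographic
  datasets are out of scope and not claimed.
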