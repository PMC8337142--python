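# Methods

## Problem

Colposcopy examines the cervix under a bright coaxial light; the mucus film
on the epithelium throws mirror-like glare — specular reflection (SR) —
into the image as small saturated-white spots. SR destroys exactly the
texture (vessel patterns, acetowhite margins) that grading of cervical
intraepithelial neoplasia depends on, and it confuses automated analysis
because acetowhite (AW) epithelium is *also* whitish: a usable SR remover
must delete glare while leaving AW strictly alone.

The pipeline runs two complementary repairs on the *same* original image
and then fuses them:

1. **Global stage** — conservative detection plus a smooth fill, robust but
   blurry;
2. **Local stage** — block-wise exemplar inpainting, texture-preserving but
   driven by a deliberately coarse detector;
3. **Integration** — per-pixel HSV maximum of the two repairs.

The stages are independent by design: the local stage never consumes the
global output, so an artifact introduced by one repair cannot propagate
through the other.

## Global stage

Detection works on normalized CIE luminance `y = Y(sRGB→XYZ, D65) ∈ [0,1]`
in two modules:

* **strong**: `y ≥ t_abs` (default 0.92);
* **soft**: `y ≥ t_soft` (0.85) **and** saturation ≤ `s_max` (0.12) **and**
  `y ≥ rel_factor ×` (median-filtered background, window `bg_window` = 31 px,
  `rel_factor` = 1.35).

The mask is strong ∪ soft. Because AW patches are large while glare is
punctate, 8-connected components whose area exceeds `max_area_frac` (1.5 %)
of the image are removed unless their peak luminance reaches
`peak_override` (0.98) — size/brightness limiting instead of gradient
features. All of these values are package defaults, chosen to encode
"small, very bright, nearly unsaturated" spots; none is a published
constant, and all are exposed in the YAML config.

Repair: each component is replaced by the mean RGB of the non-masked ring
within `ring_width` = 3 px (Chebyshev) of it; the filled image is blurred
with a σ = 8 Gaussian (radius ⌈3σ⌉, reflective borders); the blurred repair
is blended into the original under a weight field that is 1 on the mask,
decays as `exp(−d²/2·falloff_sigma²)` (σ = 4) with Euclidean distance `d`,
and is exactly 0 beyond `cutoff` = 12 px — so all remote pixels are
returned bit-identical.

## Local stage

The image is tiled into k×k near-equal blocks (k = 3, i.e. 9 blocks, by
default; sides differ by at most one pixel). Per block:

1. **Enhancement**: every pixel is scaled by `min(R,G,B)/max(R,G,B) = 1−S`.
   This dims chromatic tissue roughly by `(1−S)^2.4` in linear luminance
   while leaving near-achromatic glare untouched. A black pixel (0/0 gain)
   maps to itself; it can never be a highlight candidate.
2. **Threshold**: a pixel is specular when its CIE luminance satisfies
   `y ≥ ω · Y_global`, where `Y_global = ΣY/(ΣX+ΣY+ΣZ)` is the chromatic
   luminance of the enhanced block — a chromaticity ratio (≈ 0.31–0.33 for
   pinkish tissue) that is invariant to overall exposure, which is what
   makes the comparison a *relative* brightness test. `ω` = 1.2 by default;
   raising it strictly shrinks the mask. `Y_global` is computed per block
   (configurable to whole-image). Both `y` and `Y_global` are
   dimensionless, normalized to (0,1); only then is `y ≥ ω·Y_global`
   well-posed. A corollary worth knowing: a *uniformly* near-white block is
   entirely above threshold — such a block is reported unrepairable and
   left to the global stage.
3. **Dilation**: the mask grows by `dilate_px` = 2 (Chebyshev) before
   inpainting, so the dim halo ringing each highlight is overwritten too;
   without it the fill leaves bright rims.

Enhancement is used for detection only; inpainting operates on the original
block pixels. Blocks are disjoint (no overlap, no blending across seams);
seam artifacts are acceptable because integration fuses against the
seamless global image.

## Exemplar engine

Standard confidence/data-driven patch fill over the hole Ω with patch side
9 (odd, configurable; unit tests use 3):

* fill front = hole pixels with a known 4-neighbor, row-major;
* `C(p)` = sum of confidences of known pixels in the patch Ψ_p divided by
  the **clipped** patch area (no border penalty); confidences start at
  1 on known, 0 on hole pixels;
* `D(p) = |∇I⊥·n̂|/255` on the BT.601 grayscale of the working image. The
  gradient at p uses only currently-known pixels: central difference when
  both axis neighbors are known, otherwise the difference of the nearest
  known *pair* on either side of p (below/left pair preferred), otherwise 0
  — a one-sided difference through p itself is impossible since p is
  unknown. The front normal is the central-difference gradient of the σ = 1
  Gaussian-smoothed hole indicator, normalized; a zero normal gives D = 0.
  At a perfectly straight front this estimator often yields D = 0 (the
  missing gradient component is the along-front one); the data term then
  acts mainly at corners and curved fronts, and priority falls back to the
  confidence ordering. This is a known, accepted limitation;
* target = arg max `C·D`, ties to the earliest front pixel in scan order;
* source = the fully-known full-size window minimizing SSD over the known
  target pixels, computed in exact int64 arithmetic (no float round-off in
  the comparison), ties to the earliest window in scan order; "known"
  includes previously filled pixels;
* fill copies source pixels into the unknown target cells only; their
  confidence becomes C(target) as evaluated at selection time.

Every iteration fills at least one pixel, so the loop terminates in ≤ |Ω|
steps; non-hole pixels are never written. There is no randomness anywhere,
and the integer SSD plus fixed tie rules make the output reproducible
bit-for-bit — the test suite checks it against an independently written
brute-force reference on dozens of random instances. Search is exhaustive
within the block; at ≤ 224×224 scale this is cheap and keeps the engine
exactly equal to the reference (no ANN acceleration).

## Integration

Both repairs go to hexcone HSV (hue as a fraction in [0,1), so the three
planes are comparable); the output is the element-wise maximum of the three
planes, converted back to RGB. The round trip RGB→HSV→RGB is bit-exact for
8-bit images, which makes the merge idempotent as well as commutative.
Taking the max V slightly raises light/shade contrast rather than
suppressing brightness — at this point the glare is assumed gone, so V is
legitimate signal. Hue is maximized literally as a scalar by default; since
hue is circular this can, in principle, pick the "larger" of two hues that
are angularly close across the wrap. A `dominant_v` mode (hue of the
brighter input) is available in the config for users who want a
circularity-safe merge; it is off by default to keep the published behavior.

## Synthetic phantoms

Clinical frames have no glare-free ground truth, so quantitative claims are
made on phantoms (default 224×224): a low-frequency pink field (Gaussian
noise smoothed with σ = size/9, mapped between two pink tones), darker
random-walk vessel strokes, and

* **SR spots** (the targets): 5 ellipses, semi-axes 2–5 px, set to
  near-white *inside their support only* — V ∈ [0.98, 1], S = 0.03 — so the
  corrupted image equals the clean one exactly outside the ground-truth
  mask, and restoration error can be measured precisely where damage was
  planted;
* **AW patches** (the confounders): 2 soft-edged ellipses, semi-axes
  12–20 px, V ∈ [0.78, 0.88], S ∈ [0.25, 0.35], present in the clean image
  and absent from the truth mask. Spot centers are rejected within 3 px of
  an AW patch: the suppression measurement is only identifiable when
  targets and confounders are disjoint.

All randomness flows through the single spec seed; the same seed gives
bit-identical phantoms.

What the phantoms do *not* emulate: camera noise, glare with soft photometric
falloff outside the mask (forbidden by the exact-equality contract), specular
streaks along mucus filaments, interreflections, or true acetowhite texture.
Passing the phantom benchmark therefore demonstrates the pipeline's
*mechanics* — detection separates bright-small from bright-large, inpainting
restores plausible tissue, integration preserves untouched pixels — not
clinical-grade performance, which in the source setting could only be judged
by human raters.

A consequence of the hard-edged spots: the ω sweep's detected area is often
flat across 1.0–1.3 on phantoms (every spot pixel sits far above every
threshold). The monotone non-increase is still asserted; the *strict*
decrease seen on clinical images comes from their soft glare halos.

## Benchmark sizes

The standard benchmark (tests and `scripts/acceptance.py`) uses ten
phantoms at 224×224 with the default configuration, and cross-checks the
engine against the brute-force reference on fifty 16×16 instances with 4×4
holes at patch 3. These sizes give stable means (spot counts per phantom
vary from ~130–230 px) while a full run stays around a minute on one core.

## Numerical choices and edge cases

* sRGB→XYZ uses the D65 matrix with gamma linearization (the de-facto
  interpretation for consumer-camera RGB); luminance thresholds are on
  linear Y, not on gamma-coded value V — the two differ materially
  (V = 0.95 ↔ Y ≈ 0.89).
* 8-bit quantization is round-half-to-even everywhere (`np.rint`).
* All convolutions use reflective borders (no dark halos at image edges).
* Connected components are 8-connected (glare speckles touch diagonally).
* Degenerate inputs: all-black images have undefined chromatic luminance —
  detectors return an empty mask, the luminance accessor raises; a mask
  covering a whole image/block is unrepairable (error at the API,
  leave-unchanged fallback with a warning inside the block loop).
* Images smaller than 16 px a side are rejected at pipeline entry.
* Resizing to the working size (default 224) is bilinear.

## Known limitations

* The literal hue maximum can shift hue at pixels where the two repairs
  disagree strongly in hue; see `integrate.hue_mode`.
* Detector thresholds are tuned for pinkish, well-exposed tissue imagery;
  heavily color-cast inputs will need config adjustments.
* The exemplar search is O(block area × patch area) per iteration;
  fine for 224×224 working images, not for full-resolution frames.
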