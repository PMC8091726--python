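# Methods

## The measurement model

An in-vivo fluorescence image is a grid of non-negative integer
detector counts. The analysis assumes the image has been cropped to
the tumour and a small surrounding area, so the intensity histogram
contains (at most) three populations: imaging-bed background, the
mouse-body plateau, and the tumour signal rising above the plateau.

The pipeline is:

1. **Normalize** — divide by the image maximum, giving a surface in
   [0, 1] and recording `raw_max` for back-conversion. An all-zero
   image is rejected as degenerate.
2. **Threshold plane** — an initial level from Kapur maximum-entropy
   thresholding: the intensity histogram (256 uniform bins over
   [0, 1] by default) is split at each of the 255 candidate bin
   edges, and the level maximizing the sum of the Shannon entropies of
   the two partitions is chosen. Ties resolve to the lowest level
   (the most inclusive mask). The level is a bin edge, so the strict
   `value > level` mask criterion assigns whole bins consistently.
   The operator can override the level; the method tag
   (`auto_entropy` / `manual`) is carried into all outputs.
3. **Plane cut** — signal is strictly above the plane; pixels on the
   plane belong to background. Consequences that are part of the
   contract: a plane at 1.0 gives an empty mask, raising the plane
   never adds pixels, and the mask is invariant to positive rescaling
   of the raw counts (normalization divides the scale out).
4. **Measure in raw units** — `net_total = Σ_mask raw − raw_level ·
   area`, where `raw_level = level × raw_max` is the plane height in
   counts. Background is subtracted exactly once, through the plane.
   The elliptical background region drawn on tumour-free tissue feeds
   the k-sigma **detection call** (candidate mean above background
   mean + k·sd, k = 3 by default) and quality control; it is never
   subtracted a second time. Saturated pixels (at `2^bit_depth − 1`)
   inside the mask are counted and reported, since they under-report
   intensity.

### Connectivity and the largest-component option

All pixel connectivity in the package is 4-connected: boundary pixels
are mask pixels 4-adjacent to background or the image edge, and the
optional largest-connected-component filter labels 4-connected. The
choice matters for noisy images: with the plane at the body plateau,
about half of the plateau pixels sit above the plane by noise alone,
and 8-connected labeling (site-percolation threshold ≈ 0.407 < 0.5)
merges them into one giant component, while 4-connected labeling
(threshold ≈ 0.593 > 0.5) keeps noise clusters finite and separable
from the tumour blob. The filter is off by default — a well-cropped
image needs no cleanup and the default mask is exactly the plane cut —
and its use is recorded in run manifests.

### Known biases of plane thresholding

Threshold masks couple the mask to the data, which produces two small,
opposite systematic effects on noisy images: noise rectification
(pixels included because their noise is positive contribute a positive
bias, bounded by the largest-component filter) and flank truncation
(signal below the plane is not counted, a deficit that shrinks as the
peak grows relative to the plane). The automatic entropy plane sits on
the tumour flank, so its measurements slightly overstate fold changes
between a dim and a bright day; a plane placed at the known plateau
level removes the truncation term. Both effects are visible in the
synthetic benchmarks below and are inherent to the method, not
implementation artefacts.

## Derived statistics

- **Fold change**: ratio of group means (mean over mice at the later
  day over mean at the earlier day). A per-mouse-ratio variant is
  provided separately for individual trajectories.
- **Coefficient of variance**: 100 × sample sd / mean. Sample (n−1)
  sd is used throughout the package: group sizes are small (six mice
  per arm is typical).
- **Dilution linearity**: replicate means, background-subtracted
  (configurable) and normalized so the top dilution maps to 1; a
  log10–log10 slope fitted over the detectable dilutions (slope 1 =
  perfectly linear response) and the count of detectable dilutions as
  the linear-range extent.
- **Limit of detection**: the last dilution of the contiguous
  detectable run walking down the ladder, where detectable means the
  replicate mean exceeds background mean + k·sd of the blank wells
  (k = 3 default). The contiguity rule exists because the blank-well
  sd is itself an estimate: an isolated well three decades below the
  crossing that clears an underestimated threshold by chance is
  spurious, and accepting it would report absurd sensitivities.
- **Detection table**: earliest day each lesion was called present per
  platform, `never` when it was missed for the whole experiment.
- **Binning**: k×k blocks are **summed**, not averaged — binning
  trades resolution for per-pixel signal, multiplying a uniform field
  by k² (64 for 8×8). Factors that do not divide the image dimensions
  are rejected rather than padded so totals stay exact; block sums
  exceeding the bit-depth ceiling either clip (emulating the detector)
  or are kept in a wider container with an `overflowed` flag.
- **Calliper volume**: `(length × width²)/2`, the standard ellipsoid
  approximation for palpable tumours.

## Synthetic scenes and what they do (not) cover

`irfpquant.synthetic` renders the structure the analysis assumes: a
body plateau (default 3000 counts) above a bed level (200 counts)
inside an ellipse — or filling the frame, emulating an image already
cropped to the tumour neighbourhood — plus isotropic Gaussian blobs
(default σ = 6 px), additive Gaussian noise, integer rounding and
clipping at the bit-depth ceiling. Defaults follow the study design
where one exists: a twice-weekly imaging schedule (days 14/17/21/24),
exponential growth at ln2/3.5 per day (a doubling every 3.5 days,
giving the 4× amplitude ratio over days 17→24 used as the recovery
benchmark), tenfold dilution ladders with triplicate signal wells, and
16-bit clipping for XVI-style saturation. Where the design is silent
the generator makes its own documented choices: six blank wells per
plate (a plate has blanks to spare, and the k-sigma rule needs a
stable background sd — three blanks leave ~3% probability of a 6-fold
sd underestimate), a 96×96 px frame, and multiplicative amplitude
jitter plus sub-pixel position jitter for phantom repositioning.

Every generator emits its ground truth (discrete blob integrals,
plateau levels, realized amplitude CV, the analytic detection
crossing), so recovery tests compare the pipeline against quantities
computed independently of it. Detector noise, when enabled, is
additive Gaussian with sd proportional to signal where the benchmarks
say "x% noise" — noise that grows with signal is both the physical
regime of these detectors at high counts and the condition under which
ratio estimates from threshold masks are unbiased (a fixed absolute
noise floor biases any threshold estimator's fold change, because the
rectification term stays constant while the signal grows).

The generator does **not** simulate light transport: no depth
attenuation, scattering, autofluorescence texture, fur, or
platform-specific spectral response. Passing recovery tests therefore
show the measurement chain is correct on images with the assumed
plateau-plus-blob structure; they do not certify accuracy on deep
tissue signals, where positioning and attenuation dominate (that is
precisely the variability the phantom CV quantifies empirically).

## Numerical choices

- Histogram: 256 uniform bins on [0, 1]; empty partitions are skipped;
  entropy ties break to the lowest cut (inclusive masks); a score must
  beat the incumbent by > 1e-12 to displace it, making the tie-break
  deterministic under float noise.
- 22-bit data lives in 32-bit containers on disk and in memory;
  validation always uses the logical `2^22 − 1` ceiling.
- Sample (n−1) sd everywhere; a single-pixel background region yields
  an undefined (NaN) sd and detection calls on it are refused rather
  than silently degenerate.
- Empty masks measure as zeros, not errors; an all-undetectable
  dilution series yields an empty linear range, not an error.
- Crop boxes are 0-based half-open `[start, stop)` in (row, col)
  order; nested crops compose exactly.

## Benchmark sizes

The validation suite and the acceptance script use 96×96 px scenes
(24–64 px for pure-array properties), 10–20 repeats per phantom
series, 50–100 Monte-Carlo seeds per stochastic benchmark and 6-step
tenfold dilution plates — sizes at which every ground-truth quantity
is recovered to the stated tolerances while the whole suite runs in
seconds.

## Limitations

- The entropy threshold assumes a histogram with separable populations;
  on an uncropped whole-bed image it may lock onto the bed/body
  boundary instead of the tumour. Crop first (the workflow's first
  step), or set the level manually.
- Fold changes from the automatic plane carry the flank-truncation
  bias described above (a few percent, shrinking with tumour
  brightness); cross-day comparisons should use one consistent
  thresholding policy.
- Absolute intensities are not comparable across platforms; only
  within-platform ratios and CVs are meaningful, which is why all
  derived statistics are scale-free.
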