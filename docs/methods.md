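# Methods

## Model

Hjorth's descriptors summarize a signal by its variance and by the
variances of its derivatives. For a 1D signal they are, in spectral
terms, ratios of the spectral moments m0, m2, m4 of the power spectrum;
in the time domain they reduce to

- Activity = σ²(I),
- Mobility = σ(I′)/σ(I),
- Complexity = (σ(I″)/σ(I′)) / (σ(I′)/σ(I)).

The 2D extension used here replaces the 1D derivatives with
*non-directional derivative magnitudes*: I′ = sqrt(Ix² + Iy²) and
I″ = sqrt(Ixx² + Iyy²), pure partials only, no mixed term. Because the
magnitude is a non-negative, nonlinear function of the partials, the
exact 1D spectral-moment identities no longer hold pixel-for-pixel; the
descriptors are *defined* as the spatial-domain variance ratios above.
The package keeps one spectral identity as a numerical cross-check:
Activity equals the total power of the mean-removed image,
sum |DFT(I − mean I)|² / N², by Parseval's theorem, and the test suite
enforces agreement to 1e-9 relative.

For intuition: a pure 1D sinusoid has Mobility proportional to its
frequency and Complexity 1; broadband noise has high Mobility and
Complexity above 1; smooth long-range-correlated textures have low
Mobility. The monotone frequency response is tested on plane waves
(f = 1/64, 1/32, 1/16 cycles/pixel).

## Processing pipeline and its parameters

Each image passes through, in order:

1. **Grayscale conversion** — BT.601 luma weights (0.299, 0.587, 0.114),
   the default of most numerical imaging environments; configurable.
2. **Min–max normalization** to [0, 1]. Strictly monotone, so it changes
   no rank-based conclusion; it standardizes Activity's units across
   acquisition gains. A constant image is rejected (degenerate), never
   silently mapped to NaN.
3. **Smoothing** — the derivatives amplify pixel noise, so the
   normalized image is low-pass filtered first. Default: 3×3 unit-sum
   box filter with replicate (nearest-edge) borders; a discretized
   Gaussian (window, sigma) and reflect borders are available. The
   filter is a pluggable spec: any data-dependent coefficient rule can
   be slotted in if a particular acquisition calls for one. Replicate
   borders are the default because they introduce no artificial
   gradients at the frame.
4. **Derivatives** — central differences: (f[i+1] − f[i−1])/2 in the
   interior with one-sided differences at the two border lines for order
   1; f[i+1] − 2f[i] + f[i−1] with nearest-interior replication at the
   borders for order 2. A Sobel scheme (gain-normalized, applied twice
   for order 2) is available behind the `scheme` flag. Border rows and
   columns are *included* in all variances by default; `crop_border = n`
   removes an n-pixel frame from both the image and the derivative
   fields before the moments are taken, for border-sensitivity checks
   (the plane-wave monotonicity check uses crop_border = 2 because
   one-sided border stencils slightly bias σ(I′) at very low
   frequencies).
5. **Descriptors** — population (1/N) moments throughout. The 1/N vs
   1/(N−1) choice cancels in Mobility and Complexity; it only scales
   Activity, and is configurable (`ddof`). Descriptors are computed on
   the normalized **and filtered** image by default (`compute_on =
   "filtered"`); `"unfiltered"` skips stage 3. Activity is reported as
   the raw variance of normalized intensities, with no image-size
   normalization.

Descriptors are computed per whole image; there is no tiling or
region-of-interest logic, since the unit of analysis is one pollen-grain
micrograph.

## Group statistics

The differentiation procedure mirrors standard practice for small,
non-normal grouped samples:

- **Shapiro–Wilk** per group and **Levene** across groups are computed
  first as assumption checks for a parametric ANOVA. Levene is reported
  with its full one-way ANOVA decomposition on absolute deviations
  (SS, df, MS between; SS*, df*, MS* residual; F = MS/MS*). Center =
  group mean by default (classic Levene); median gives Brown–Forsythe.
  No parametric ANOVA decision path is provided: with these assumption
  checks failing, the decision statistic is rank-based.
- **Kruskal–Wallis**: pooled mid-ranks (ties averaged), H = [12/(N(N+1))
  · Σ R_i²/n_i − 3(N+1)] / (1 − Σ(t³−t)/(N³−N)), referred to χ²(k−1).
  Rank conservation Σ R_i = N(N+1)/2 is asserted on every input. The
  χ² reference is an approximation that is conservative at very small N;
  `method="permutation"` computes the exact null by full enumeration of
  group assignments and is intended for total N ≲ 12.
- **Dunn's post hoc** z-tests on rank means with standard error
  sqrt(N(N+1)/12 · (1/n_i + 1/n_j)), two-sided normal p, Bonferroni
  factor k(k−1)/2 clipped at 1. This specific variant was chosen because
  it exactly reproduces the published pairwise p-values of the
  three-taxa worked example from that table's rank sums — the
  reconstruction is the justification, and the worked-example test pins
  it. Note the reconstruction must start from the exact rank averages
  R_i/n_i; the table's 3-decimal rank averages are truncated and give
  p-values off in the 6th decimal.
- Tie correction is part of `kruskal_wallis` (descriptor values are
  continuous, so it is usually 1); the worked-example path
  `kruskal_wallis_from_ranks` defaults to no tie correction, which is
  the form the published H values satisfy.

## Synthetic cohorts

The micrograph database behind the three-taxa example is not deposited,
so the package generates its own cohorts:

- **Plane waves** — analytic single-frequency textures for calibration
  tests (period, amplitude and direction known exactly).
- **Gaussian random fields** with power-law spectra S(ω) ∝ |ω|^−β:
  white Gaussian noise shaped in the Fourier domain by |ω|^(−β/2),
  mean-removed, scaled to a target standard deviation, offset to
  non-negative. β = 0 is white noise (fine granularity), β = 2 a smooth
  long-range-correlated texture (coarse granularity). A generator sanity
  test recovers β from the radial periodogram slope to ±0.3.

The default study cohort uses β = 0/1/2 at group sizes 18/8/9 and
256×256 8-bit images, matching the sample design and acquisition depth
of the motivating three-taxa study; images are written as 8-bit PNG
(min–max scaled), with a float-TIFF option preserving exact values for
oracle tests. Per-image seeds are a stable SHA-256 hash of
(master_seed, group label, index), so adding a group never changes
existing groups' images, and a manifest (image_id, group, seed) suffices
to regenerate any cohort bit-identically.

What the synthetic cohorts do **not** emulate: optical blur, uneven
illumination, grain-boundary geometry, staining variability, or any
pollen morphology. Passing tests therefore demonstrate that the
descriptor/statistics machinery detects controlled second-order
(variance and spectral) differences at the study's sample sizes — not
that real pollen taxa are separable; that evidence must come from real
micrographs.

## Numerical and design choices

- Degenerate inputs raise typed errors rather than produce NaN:
  constant images (normalization, Mobility), zero first-derivative
  spread (Complexity), all-identical samples (Kruskal–Wallis), zero
  residual deviation spread (Levene).
- The nearest-centroid leave-one-out classifier is deliberately minimal
  and labeled exploratory: z-scores are fit on the training fold only,
  zero-variance descriptors are dropped with a warning, centroid ties
  break by group order. The package's scientific surface is the
  statistics, not classification accuracy.
- Batch extraction never drops a failing image silently: failures are
  logged, collected, and signalled via a partial-failure exit status in
  the CLI.
- p-values are kept at full double precision in JSON output; rounding
  happens only in the Markdown report writer.
- Test problem sizes: oracle-equivalence and Parseval checks use random
  images up to 64×64 against a loop-based reimplementation; end-to-end
  cohort tests use 128×128 (unit suite) and 256×256 (acceptance script)
  images, sizes at which the group separation is already decisive.

## Known limitations

- The 2D descriptors inherit no exact spectral-moment interpretation
  (see above); they are empirical texture features.
- The χ² reference for H is approximate below ~5 observations per
  group; use the permutation option there.
- The data-dependent smoothing-coefficient rule used by some
  acquisition pipelines is not specified anywhere reproducible; the
  default here is a fixed 3×3 box filter, and the smoothing spec is the
  extension point for alternatives.
- Whole-image descriptors conflate grain and background texture if the
  input is not already a cropped single-grain image.
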