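# Methods

## Visual model

The receptor-noise-limited (RNL) model predicts discriminability of two
stimuli from receptor signals and channel noise. For receptor class *i*
with spectral sensitivity `R_i(λ)`, surface reflectance `S(λ)`, and
illuminant `I(λ)`, the quantal catch is `Q_i = ∫ R_i S I dλ` (trapezoidal
rule on a common 1-nm grid, 300–700 nm — the visual range of most diurnal
lizards and the resolution scale of field spectrometers; finer steps
change catches by far less than measurement noise). Log receptor contrast
against the adapting background is `Δf_i = ln(Q_i / Q_i^bg)`; because
catches enter only as ratios, any rescaling of the illuminant cancels
exactly (tested as an invariant).

Chromatic distance for *n* receptor classes is

    ΔS² = Σ_{i<j} (Δf_i − Δf_j)² Π_{k∉{i,j}} ω_k²  /  Σ_i Π_{k≠i} ω_k²

which reduces to `|Δf₁ − Δf₂| / √(ω₁² + ω₂²)` for a dichromat and to the
familiar tri-/tetrachromat expressions. An equivalent derivation — the
generalized-least-squares distance of Δf from the achromatic
(all-channels-equal) axis under noise covariance diag(ω²) — is coded
independently in the tests and must agree to 1e-9 on random draws. A
consequence of that geometry: ΔS is minimized when one channel sits at
the *noise-weighted* (1/ω²) mean of the others, not their arithmetic
mean, and grows monotonically as the channel moves away from that point;
the property test asserts exactly this.

Achromatic (luminance) distance uses the long-wave channel alone:
`ΔL = |ln(Q_LWS/Q_LWS^bg)| / ω_ach` with ω_ach = 0.05. The natural log of
ΔL is taken only in the statistics stage (to stabilize variance), never
inside the model; it is undefined (reported as NaN) when ΔL = 0.

Defaults describe a tawny-dragon-like tetrachromat: λmax 365 (UVS),
440 (SWS), 493 (MWS), 571 (LWS) nm; relative abundances 1 : 1 : 3.5 : 6;
ω_LWS = 0.1 with the square-root-of-abundance rule
`ω_i = ω_ref √(η_ref/η_i)` for the rest (noise pools over the receptors
feeding a channel), giving ω = {0.245, 0.245, 0.131, 0.100}.

Design choices where the problem was genuinely open:

* **Pigment curve shape.** Only λmax values are specified by the target
  visual system; curves use the Govardovskii et al. (2000) A1 nomogram
  alpha band, the field standard for reptile visual modeling. The UV-side
  beta band is available but off by default, and no ocular-media
  transmission correction is applied; both are deliberate omissions kept
  pluggable.
* **Background and adaptation.** Contrasts are computed against a flat
  99% white standard which is simultaneously the adapting background (the
  ratio in Δf is the only chromatic adaptation applied).
* **Irradiance.** Flat by default; results depend on the illuminant
  shape, so callers measuring under real light should supply their own
  spectrum (CSV, `wavelength_nm,value`), which is recorded in outputs.

## Image pipeline

Cameras apply a roughly power-law transfer to scene radiance. Per
channel, `response = a·reflectance^(1/γ) + c` is fitted by least squares
to the six gray-checker patches (reflectances 0.03…0.90) and inverted
analytically; non-monotone patch responses trigger a warning and a
shape-preserving monotone (PCHIP) spline fallback, duplicate responses
are an error. Equalization multiplies each channel by
(reference reflectance / channel mean over the chosen gray patch) —
idempotent, and by construction removes any per-channel illuminant gain.

Pixel classification happens in linear, equalized RGB. With
chromaticities `r = R/(R+G+B)` etc., the orange score is `r − g` and the
yellow score `(r+g)/2 − b`; orange is tested first at the stricter 0.20
threshold, then yellow at 0.15, else gray. The published analyses this
mirrors state the thresholds but not the score functions, so the scores
are a documented design choice and the classifier is pluggable; recovered
proportions on real photographs may shift under a different published
score. Both scores are exported per pixel for audit. All-zero pixels are
excluded rather than forced into a class.

## TEM morphometry

Masks are pre-labeled (background, epidermis, iridophore, melanophore,
xanthophore-or-collagen, platelet, platelet hole, cytoplasm) and assumed
pre-rotated so the epidermis is horizontal; "vertical" transects are
image columns starting at the per-column dermal boundary. A transect
spans 15 µm of depth at 5 µm lateral spacing; its intersection proportion
counts iridophore, platelet, and hole pixels (holes are merged with
platelets throughout — sectioning can pluck crystals but the footprint
remains). Transects whose span leaves the image or crosses background are
dropped and counted, not rescaled: rescaling partial transects would bias
density toward superficial layers. The per-sample summary is the median
across transects (even counts: mean of the central pair).

Platelet packing uses square 1×1 µm plots placed at seeded-random,
non-overlapping positions wholly inside iridophore material (greedy
acceptance over a shuffled candidate list found via a summed-area table);
each plot reports (platelet + hole) / total pixels and the per-sample
summary is the median. If fewer plots fit than requested, as many as fit
are placed with a warning.

The depth profile reports, per pixel row of depth (centers, in µm), the
fraction of transects whose pixel at that depth is iridophore material;
the peak is the argmax with ties broken toward the shallowest depth.

Rescaling a mask by an integer factor (with the pixel size adjusted)
leaves every proportion unchanged exactly — tested as an invariant.

## Synthetic data

Generators are pure functions of (spec, seed); ground truth always comes
back with the data.

* **Spectra.** Orange/yellow are logistic long-pass cut-ons (cut-on
  565 nm vs 505 nm, widths 25/20 nm, amplitude ≈0.45–0.5 over a ≈0.05
  base, with seeded jitter); dark gray/cream are flat at 0.08/0.55; the
  white standard is flat 0.99 exactly.
* **Throat scenes.** Smoothed seeded noise is rank-thresholded so class
  pixel counts hit target proportions exactly (±1 pixel from rounding);
  default proportions (0.77 gray / 0.15 orange / 0.08 yellow) echo a
  typical pre-treatment throat. Class RGB means sit far (>10 σ of the
  0.01 within-class noise) from the classification boundaries, so
  recovery through the full camera path is exact by construction — which
  is the point: the benchmark isolates the calibration arithmetic, not
  classifier robustness. The camera model applies gain, γ = 2.2,
  offset, optional Gaussian noise, and 16-bit quantization; six neutral
  checker patches and JSON annotations are embedded.
* **Micrographs.** A 80×22 µm canvas at 0.02 µm/px (TEM scale): epidermis
  band, iridophore ellipses (4.5×2.5 µm) added in the 5–12 µm depth band
  until the 15-µm-window column fraction reaches its 0.30 target,
  melanophore decoys deeper, collagen/xanthophore matrix elsewhere.
  Platelets are rotated rectangles (0.5×0.1 µm, orientation-jittered)
  laid quasi-ordered on a jittered lattice sized for the target fill and
  topped up randomly until each *merged* iridophore component reaches the
  target — per-component layout prevents overlapping cells from doubling
  the local density, and the quasi-ordered arrangement (matching how
  these platelets actually look) keeps plot-to-plot sampling variance
  low. Default fill 0.40, typical of gray/yellow skin; a 0.288 scenario
  reproduces cream-skin packing. Achieved fractions are reported from
  pixel counts of the finished mask, not from the targets.
* **Longitudinal tables.** Response = cell mean + Normal(0, σ_id²)
  individual intercept + Normal(0, σ²) residual, over 12 + 11 individuals
  × three timepoints. The default cell means encode a ≈6.27 JND
  achromatic decline in the treated arm with flat controls; σ_id = 4.0
  and σ = 3.0 JND give cell-mean standard errors ≈1.4–1.7, matching the
  scale reported for such designs.

What passing these benchmarks does *not* show: real photographs have
spatial illumination gradients, chromatic aberration, and class-boundary
pixels; real TEM masks have annotation error and tilted epidermis; real
spectra have sensor noise. The generators deliberately omit those
effects, so the tests certify the estimators' arithmetic and calibration
behavior, not field robustness.

## Statistics

`fit_lmm` fits a random-intercept linear mixed model by REML
(statsmodels MixedLM). Fixed-term tests divide the Wald statistic by its
numerator df and refer to an F distribution with containment-style
denominator df = n_obs − rank(X) − (n_groups − 1), the convention of
classic mixed-model ANOVA on balanced longitudinal designs (for the
default 23 × 3 design this gives df 2,41 for the interaction). LS-means
are model predictions on the factor grid with delta-method SEs; pairwise
time-within-treatment contrasts are Bonferroni-adjusted with raw p-values
retained. Under the null generator the interaction test's empirical
type-I error sits at the nominal 5% within Monte-Carlo tolerance
(checked over 200 replicates).

Noiseless data (zero residual variance) make the mixed likelihood
singular; the fit detects this and falls back to ordinary least squares,
whose fixed-effect solution on a balanced saturated design is the exact
cell means (SEs reported as 0). An optional natural-log transform of the
response is applied before fitting (used for achromatic contrast);
back-transformed LS-means are labeled geometric-scale.

Problem sizes throughout the test and acceptance runs (1000 RNL draws,
50 brute-force masks, 100 fill-recovery seeds, 200 null replicates,
compact 30×20 µm micrographs for the repeated-generation studies) were
chosen to keep Monte-Carlo error comfortably inside the asserted
tolerances while the full suite runs in about a minute.

## Known limitations

* Viewing geometry, fluorescence, polarization, and ocular media are not
  modeled; JNDs are as good as the supplied irradiance spectrum.
* The pixel-score definitions behind the segmentation thresholds are a
  design choice (see above); absolute proportions are comparable within
  this pipeline, not across score conventions.
* Transect placement assumes a horizontal epidermis; strongly curved
  sections must be rectified upstream.
* Denominator-df conventions for mixed models differ across packages;
  the containment rule used here is reported in every output and exact
  df/p agreement with other software is not guaranteed.
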