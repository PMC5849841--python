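# Methods

`sonoqa` measures three quantitative image-quality metrics from scan-converted
B-mode phantom images — contrast response, depth of penetration (DOP), and
−6 dB spatial resolution — and provides the statistics used to assess such
measurements in a QA program (stability, sensitivity, repeatability,
semi-automated success rate).  A speckle-phantom simulator with analytic
ground truth serves as the validation bed for every measurement.

Throughout the package, dB means amplitude decibels (20·log₁₀).  Images are
8-bit by default (`bit_depth` is a field, so 10/12-bit captures work
unchanged); row 0 is the shallowest depth and physical depth is
`depth_offset + row · axial_spacing` (mm).  Every measurement screens its
region of interest for pixel saturation (pixels at the top code value) and
carries the flag in its result; the default tolerance is 0.1% of ROI pixels,
because a strict-zero rule is brittle against single stray pixels on real
captures.  The threshold is configurable down to zero.

## Gray-map linearization

Scanners display compressed echo level through a gray map that is usually
nonlinear.  All pixel-value-based measurements here operate on *linearized*
levels: an inverse LUT is extracted from the on-screen grayscale ramp by
averaging the ramp strip along its narrow axis, monotone-regularizing the
observed transfer curve with a pool-adjacent-violators fit, inverting it
(positions assumed linear in display input), and normalizing the endpoints to
the full code range.  A strip spanning less than half the code range is
rejected as degenerate; a curve deviating from its monotone fit by more than
4 gray levels RMS (default) is rejected as non-monotone.  When no ramp is
available the LUT defaults to identity with a warning — the recommended
practice is to select the most linear gray map the scanner offers.

## Contrast response

The contrast response is the slope, in gray levels per dB, of mean linearized
gray level versus nominal target contrast over three or more cylindrical
targets of known echogenicity.  Target centers are refined by maximizing the
absolute disc-minus-annulus mean difference within ± half a diameter of the
nominal position (computed with FFT convolutions); the measurement disc is
70% of the nominal diameter to exclude boundary partial-volume pixels, and
the background annulus spans 1.2–1.8 target radii at the same depth.

A target is declared undetected when its refined score is below 4 local
standard errors of the annulus mean.  (A 2× threshold is tempting but wrong
here: the refinement maximizes the score over a search window, which inflates
the null maximum on target-free speckle to ~2–3 standard errors; 4× keeps
false alarms negligible while real targets score an order of magnitude
higher.)  Failed targets must be supplied manually, which the result records
as `detection_method="manual"` — the input to success-rate accounting.

The regression is ordinary least squares of mean gray versus nominal dB (the
intercept absorbs the background level), with r² reported.  When the
acquisition settings carry a displayed dynamic range DR, the predicted slope
256/DR (8-bit code range over displayed dB span) is reported alongside.  The
fitted slope is also the pixel→dB calibration used by the resolution
measurement.

## Depth of penetration

DOP is the depth at which the depth-wise SNR from a same-settings gel/air
image pair falls to 1.  This package's estimator dialect: linearized pixels,
4-row depth bands, the central 50% lateral window, band SNR = (mean gel
level)/(mean air level) with the noise mean floored at 1 linearized level,
and the crossing of the threshold located by linear interpolation in
log(SNR) versus depth.  All four choices are configurable.  A profile that
never crosses is censored at the deepest analyzed band; one already below
threshold at the first band returns the first depth with a shallow-penetration
warning.  Because both members are linearized first, the result is gray-map
independent by construction, and a gain change common to both members cancels
in the ratio.  Repeated acquisitions are combined by averaging per-pair DOP
values (mean ± sample SD over the usual six pairs), not by averaging pixels.

## Spatial resolution

A thin nylon filament imaged in cross-section approximates the point-spread
function.  The width at a pin is measured on the linearized profile through
the sub-pixel peak (3-point parabolic refinement; the profile is averaged
over 3 pixels orthogonally to suppress speckle spikes), at the threshold
`peak − 6·slope` gray levels, where `slope` is the contrast-response
calibration — i.e. the 6 dB drop is evaluated on the compressed pixel scale,
so the measurement tracks the scanner's compression and gray map.  The
calibration is passed explicitly, so it may come from the same image or from
a stored measurement.

Crossings are the *outermost* ones adjacent to the peak: after the profile
falls below the threshold, the scan continues for another 1 mm (configurable
`lobe_gap_mm`); any re-rise within that gap — a speckle dip or a sidelobe —
extends the lobe and sets a `multi_lobe` flag.  Structure farther away than
the gap (e.g. the neighboring pin of the column on an axial profile) is not
attributed to the pin.  A profile that does not fall below threshold before
the image edge raises a truncation error; a saturated peak is flagged.

Pins are detected as local maxima of the residual after subtracting the
per-row median of the linearized image (the pin column occupies a small
fraction of each row, so the row median tracks the depth-dependent background
while ignoring pins), within ±3 mm of the expected positions, with a
4-robust-SD (MAD-based) acceptance threshold.  Zero detections is a failure
status prompting manual input, not an exception.

Elevational resolution (slice thickness) uses the 45° filament protocol: with
the scan plane intersecting the pin column at 45°, the in-plane streak length
of each pin equals the slice thickness, so the elevational width is the
lateral width measured on the tilted acquisition, with no geometric
rescaling.  The streak convolves the in-plane beam in quadrature, so the
estimate is biased high when the lateral beam is not narrow; a warning is
emitted when the lateral width at the same depth reaches 1/√2 of the
elevational estimate (i.e. contributes at least half the quadrature sum).

For parameter trending, a single reference pin is used: the pin closest to
the observed focal depth, or — when no clear focus exists — closest to half
the DOP; ties break toward the shallower pin.

## QA assessment statistics

* **Stability**: signed percent deviation from baseline,
  `100·(variant − baseline)/baseline`; a deviation within ±10% (boundary
  inclusive) passes.  Percent error is baseline-referenced and deliberately
  not antisymmetric under swapping.
* **Sensitivity**: monotone expectations (DOP falls with output power and
  rises in a less attenuating background; resolution improves with transmit
  frequency) are judged by the net change relative to baseline with a ±5%
  flat band; contrast response is regressed against the predicted 256/DR and
  "follows" requires a positive slope significant at α = 0.05.
* **Repeatability**: coefficients of variation, always with the sample
  (n−1) standard deviation.  The inter-operator CV is the CV of operator
  means by default; a pooled variant (CV over all values) is available.
* **Success rate**: fraction of measurements completing without manual
  intervention.

## The simulator

The simulator renders a CIRS 040GSE-like scene: each pixel carries a complex
echo amplitude whose speckle component is circular complex Gaussian with
Rayleigh envelope scale `A0 · 10^(−2αf·z/20)` (round-trip attenuation; α in
dB/cm/MHz one-way, matching phantom labeling), multiplied by `10^(c/20)`
inside a contrast cylinder of nominal contrast c.  Pins add deterministic
Gaussian amplitude blobs coherently to the in-phase component, 30 dB above
background by default so detection is unambiguous.  Electronic noise is an
independent complex Gaussian of per-component RMS N0, giving a Rayleigh
envelope of scale N0 in air.  The envelope is amplified (gain, optional TGC),
log-compressed at `s` gray levels/dB with the reference amplitude at the top
code (`s = 256/DR` links the slope to displayed dynamic range), quantized,
clipped, and passed through the configured display gray map; an on-screen
ramp strip can be painted into the frame for the LUT extractor.  Identical
(config, seed) pairs are bit-identical.

Ground truth is analytic: the expected contrast slope equals `s`; the −6 dB
width of a Gaussian pin of width σ is 2.3508·σ (from
`exp(−x²/2σ²) = 10^(−6/20)`); the tilted-scene streak has apparent
σ = √(σ_elev² + σ_lat²); and with A0 and N0 both Rayleigh scale parameters
the mean-envelope factors cancel in the gel/air gray ratio, so the SNR=1
crossing is exactly `z* = 20·log₁₀(A0_eff/N0)/(2αf)` cm, with A0_eff scaled
by √(power/100).

One deliberate modelling choice: by default the gel member of a DOP pair is
rendered **speckle-only**, with the noise floor only in the air member.  A
gel image carrying the same additive noise floor as the air image can never
fall below it in mean gray level — the ratio approaches 1 asymptotically and
the ratio-based estimator would always censor — whereas the speckle-only gel
yields the closed-form crossing above.  An opt-in `noise_in_gel` flag exists
for realism experiments with other estimator dialects.

What the simulator does **not** emulate: lateral/axial speckle correlation
(speckle is per-pixel white, not convolved with a point-spread function),
scan-conversion geometry of curved and sector probes (all rasters are
linear-geometry), nonlinear propagation, reverberation and clutter, and
scanner-side processing such as adaptive gain.  Passing tests therefore
demonstrate that the analyzers recover known answers under ideal speckle
statistics, not that any particular scanner behaves ideally.

## Default study conditions

The preset scenes fix the conditions used by the validation suite and the
acceptance script:

* **Contrast** — four 8 mm cylinders of −6/−3/+3/+6 dB at a common 30 mm
  depth, 0.7 dB/cm/MHz background at 5 MHz, compression 5 gray/dB (DR
  51.2 dB), 0.1 × 0.15 mm pixels, ramp strip along the right edge.  The
  common depth makes attenuation a pure intercept term.
* **DOP** — plain 0.7 dB/cm/MHz gel at 5 MHz, 70 dB initial amplitude SNR
  (crossing analytically at 10.0 cm), DR 90 dB so the noise floor stays on
  scale, 12 cm × 5.8 cm field at 0.25 × 0.3 mm pixels (4-row bands = 0.1 cm),
  12 dB compression headroom so the shallow Rayleigh tail does not saturate.
* **Resolution** — seven pins every 10 mm at 25 mm lateral, σ_axial 0.25 mm
  depth-constant, σ_lateral an hourglass with 0.6 mm waist at the 40 mm
  focus, σ_elevational an hourglass with 1.2 mm waist at the same focus,
  0.06 mm pixels (≈ σ_axial/4), DR 90 dB.  Six seeds per condition mirror the
  six-acquisition averaging protocol.

These sizes keep a full validation run (test suite plus acceptance script)
in the tens of seconds on a single CPU while leaving every quantity several
sampling standard errors inside its tolerance.

## Numerical choices and degenerate inputs

Band means are floored at 1 linearized level before division; SNR values are
floored at 10⁻⁶ inside the log-interpolation; a threshold hit exactly at a
band is returned at that node.  The contrast regression with zero response
variance returns slope 0, r² 0 and a "no contrast discrimination" flag rather
than NaN.  Parabolic peak refinement is clamped to ±0.5 samples and falls
back to the grid maximum when the 3-point stencil is not concave.  Detection
tie-breaks go to the candidate closest to the nominal position (targets) and
to the shallower pin (reference-pin selection).

## Known limitations

Success-rate numbers from simulation say nothing about automation success on
clinical scanner captures, where target contrast, clutter and annotations
differ; the detector thresholds are honest defaults, not tuned to any
scanner.  The elevational estimate inherits the 45° protocol's in-plane
broadening; no deconvolution is attempted.  Censored DOP values (profile
never crossing within the imaged depth) are reported at the maximum analyzed
depth and flagged — they are lower bounds, and trend comparisons that involve
censored values should be read accordingly.  The IEC-style SNR estimator is a
documented dialect: mean/mean band statistics on linearized gray levels;
other dialects (mean/SD, dB-domain differences) are not implemented.
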