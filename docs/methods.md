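# Methods

`cymage` quantifies single-molecule TIRF movies of dye-labelled membrane
proteins: how many fluorescent spots per µm² of membrane, how many
fluorophores per spot (via photobleaching step counting), and whether two
spectrally distinct labels co-occur beyond chance. Because the raw oocyte
image stacks behind the original study are not publicly deposited, the
package ships a synthetic movie generator with exact ground truth; every
stage of the analysis is validated against that truth.

## Synthetic movie model

A movie is a T × H × W stack, one per channel (Cy3, Cy5), 16-bit grayscale.
Ground truth per channel is a list of spots, each with a continuous
position, a fluorophore count n ∈ {1..K}, and one bleach frame per
fluorophore.

**Spot placement.** Spot counts are Poisson(density × area) with uniform
positions (complete spatial randomness, CSR). A Binomial(n_Cy5, f) subset
of Cy5 spots is instead placed at distinct Cy3 positions displaced by the
channel registration offset; `f` is the true dual-colour fraction.
Truly colocalized spots are modelled as position-identical dual-colour
spots — whether they represent one labelled dimer or a cluster is not
modelled.

**Condition presets.** The `encoded` preset uses Cy3 0.14 and Cy5 0.08
spots/µm², a fluorophore-count distribution (0.35, 0.30, 0.20, 0.10, 0.05)
over 1–5 labels, and f = 0.14. The `mock` (background) preset uses 0.03 and
0.02 spots/µm², counts (0.85, 0.12, 0.03) — single-label dominated — and
f = 0. The exact mock mass on one step is a design choice (≥ 0.8).

**Photophysics.** Each fluorophore bleaches independently after an
Exp(rate) exposure time; the default rate 0.03 s⁻¹ at 1 frame/s leaves ~5%
of fluorophores alive after a 100-frame movie. The bleach frame is
`1 + floor(t/Δt)`: the bleaching clock starts at illumination onset, so
every fluorophore is alive in frame 0 — the detection frame — and the
earliest observable step is frame 1. Blinking (a reversible one-frame dark
excursion) is off by default and available as `blink_prob` in
`simulate_bleach_trace`; there is no dark-state recovery model.

**Camera.** Each live fluorophore contributes a pixel-integrated 2-D
Gaussian (error-function differences, not point samples). The default PSF
width is 0.65 px: at the preset pixel size of 0.2 µm/px this is a 130 nm
Gaussian sigma, the Airy-core approximation σ ≈ 0.21 λ/NA for a 1.49 NA
TIRF objective at Cy3/Cy5 emission wavelengths. The pixel size itself is
arbitrary (the study never states it) and required wherever areas are
computed; 0.2 µm/px is a plausible 60× EMCCD scale. Background is a planar
ramp (offset 100 AU, gradients 0.05/0.08 AU/px); noise is Poisson shot
noise (gain 1 AU/photon) plus Gaussian read noise (3 AU). The default
single-fluorophore intensity of 2400 AU integrated over the PSF puts the
brightest pixel of one fluorophore (~300 AU) clearly above the detection
thresholds (130–190 grayscale units) with its 4-neighbours above threshold
too, so the area filter is meaningful. Outputs are clipped to 16 bits and
clipping is flagged. Per-channel background offsets are exposed, but the
longer-wavelength dependence of TIRF background is not modelled.

**Seeding.** One master seed per dataset; stage-specific generators are
spawned deterministically (`numpy` `SeedSequence`), so datasets are
bit-reproducible.

## Background subtraction

The background of a frame is its grayscale morphological opening with a
ball (spherical-cap) structuring element of radius 50 px, erosion then
dilation via `scipy.ndimage`. This operator is anti-extensive
(background ≤ frame), idempotent, and exact — unlike ImageJ's paraboloid
approximation with pre-smoothing, which it otherwise emulates; a 3×3 mean
pre-smoothing flag exists but is off by default. The ball's intensity scale
is 1 AU/px (configurable). Background is estimated on the first frame and
reused across the stack by default (spots bleach; the background is static
in this model); per-frame estimation is available.

Two numerical consequences matter downstream:

- An opening of a noisy surface rides the *lower envelope* of the noise,
  sitting ~3σ below the true background plane. Subtraction therefore
  leaves a small, smooth positive residual everywhere.
- Default subtraction clips at zero (the display convention); quantitative
  trace extraction must use `clip=False`, otherwise rectified noise biases
  integrated intensities upward and bleached traces never average to zero.

The pipeline handles both by extracting traces from unclipped residuals
and anchoring each AOI to the per-frame median of a 3-px annulus around
its window (robust to neighbouring spots), a standard single-molecule
(CoSMoS-style) local background correction. Detection runs on the clipped
first frame, where thresholds in grayscale units are meaningful.

## Spot detection and density

On the background-subtracted first frame, pixels at or above the intensity
threshold (presets: Cy3 170, Cy5 140 — midpoints of the stated 150–190 and
130–150 unit ranges) form 8-connected components; components with area in
[2, 49] px become AOIs: fixed 7×7 windows centered on the
intensity-weighted centroid rounded to the nearest pixel (floor(x + 0.5),
which keeps detection translation-equivariant). Centroids closer than
4 px (Chebyshev) merge keeping the brightest; windows that would leave the
frame are discarded; ordering is by (row, col). Raising the threshold
never increases the count for isolated spots, but merging/splitting of
touching components means strict monotonicity does not hold on arbitrary
images.

Density is count/area. The plain estimator divides by the full frame area;
the pipeline uses the edge-corrected denominator (H−6)(W−6)px² — the
region where a 7×7 window fits — since border spots cannot be counted.

**Resolution limit.** At the encoded Cy3 density (0.14 spots/µm² =
0.0056 spots/px² at 0.2 µm/px), ~19% of true spots have a neighbour within
4 px; supra-threshold footprints of neighbours touch within ~3 px and
merge into one component. Threshold/connected-component detection therefore
undercounts by ~8–12% at that density (and proportionally less at mock
densities). The recovery tests compare mean per-movie counts at the
single-movie Poisson scale (|Δ| ≤ 2√λ), the unit of observation in this
kind of experiment; a pooled estimate over many movies resolves the
blending bias, which is physical, not algorithmic. Traces extracted from
blended AOIs also sum the fluorophores of both spots, slightly fattening
the upper tail of the step-count distribution.

## Trace extraction and step counting

A trace is the 7×7 window sum per frame (optionally locally
background-anchored, above). The noise scale σ is estimated as
1.4826·median|Δx|/√2 — the MAD-normal scale of successive differences,
insensitive to sparse steps.

Steps are counted by a penalized piecewise-constant fit minimizing

    SSE + λ σ² log(T) · k,   λ = 3 by default,

over all change-point sets, subject to each adjacent-level jump having
amplitude ≥ 2σ (`min_step_snr`). The optimum is computed exactly by
dynamic programming over segmentations: because the amplitude constraint
only couples adjacent segments, the last segment's boundary pair is a
sufficient state (O(T³) time, O(T²) memory; ~30 ms at T = 100). A
vanishing per-step tie-break surcharge prefers the sparsest of equal-cost
fits, so noiseless staircases are recovered exactly. A brute-force
enumerator over all admissible change-point sets serves as an independent
cross-check in the tests.

Classification replaces the study's manual scoring with explicit rules:

- any upward fitted transition → trace rejected (`upward_step`;
  blinking or aggregation);
- final level farther than 3σ/√(segment length) from zero → rejected
  (`never_bleached`; only traces bleaching to completion count);
- otherwise accepted with `n_steps` = number of downward transitions.

A slow monotone drift large relative to σ can register as steps (upward
drifts are rejected by the first rule); manual classification has the same
failure mode. Sub-unit "crosstalk" steps from a neighbouring spot's PSF
tail inside the window pass the 2σ gate if large enough; they are a known
contaminant at high density.

Histograms: absolute counts pool all movies of a condition (the pipeline
uses equal movie counts per condition by construction); relative
frequencies are computed per movie, averaged per oocyte, and pooled as
mean ± s.e.m. across oocytes. Conditions are compared per step number with
the two-sample equal-variance two-tailed t-test on per-oocyte frequencies.

## Colocalization and the rotation null

Cy5 AOI centers are mapped onto the Cy3 field by subtracting the channel
registration offset — treated as a known instrument calibration and passed
into the pipeline. `estimate_registration_offset` (cross-correlation of
binned spot maps) recovers the offset to ≤ 1 px when genuine dual-colour
structure exists, but on a mock condition the maximum over candidate
shifts mines chance overlap and inflates the apparent colocalization
severalfold, so free per-movie estimation is deliberately not the default.

A Cy5 spot is colocalized when ≥ 1 Cy3 AOI center lies within Chebyshev
distance 2 px (square windows match the square AOIs; 2 px covers the
stated 1–2 px mapping error). No exclusive matching; no intensity
criterion on the Cy3 partner. Fractions are per frame, averaged per
oocyte, pooled as mean ± s.e.m.; frames with no Cy5 spots are excluded
with a warning.

The random-colocalization null rotates the Cy5 pattern 90° about the image
center — (r, c) → (c, S−1−r) within the largest centered square, dropping
points outside it for non-square frames — and re-scores. Rotation is an
isometry, preserving density and internal structure while destroying
cross-channel correspondence. For pixel-anchored AOIs on CSR channels the
expected fraction is 1 − exp(−λ(2r+1)²·px²): ~3% at mock densities, but
~13% at the encoded Cy3 density with the default pixel size and tolerance
— random overlap scales with density × window area, which is why both the
observed and the null fraction must be reported. The package reports the
uncorrected and the null-subtracted fraction; with injected dual-colour
fraction f the null-subtracted estimate converges to f(1 − p) ≈ f.

## Closed-form quantifications

- **Ligation (acylation) efficiency**: A_dye·ε_RNA/(A_RNA·ε_dye)·100, with
  ε = 696,100 M⁻¹cm⁻¹ (THG73 tRNA, 260 nm), 150,000 (Cy3, 550 nm),
  250,000 (Cy5, 650 nm). The dye wavelength is bound to the dye label.
  LD550's coefficient is vendor-withheld and must be supplied. Values
  >100% are allowed (measurement noise). Degree-0 homogeneous in the
  absorbances.
- **Percent of control**: 100·signal/control; full precision internally,
  rounding only for display.
- **Fold over background**: mean(test)/mean(background), s.e.m. by the
  delta method (the original's error propagation is unstated; the delta
  method is verified against a bootstrap in the tests).
- **Decay to a fraction**: peak = max |I| after a configurable stimulus
  onset; time to the first sample at ≤ fraction·|I_peak|, linearly
  interpolated; drops completing within one sampling interval report 0;
  traces that never reach the threshold are flagged. Amplitude-invariant.
  For an exponential with time constant τ the 10% time is τ·ln 10.
- **t-test**: pooled-variance two-sample two-tailed Student's t from the
  closed form (df = n₁+n₂−2), verified against `scipy.stats.ttest_ind`;
  zero pooled variance with equal means gives t = 0, p = 1, with unequal
  means is flagged degenerate.
- **mean ± s.e.m.**: hierarchical — per-group (oocyte) means first, then
  mean and s.e.m. across groups; a single group has undefined s.e.m.

## Problem sizes and known limitations

End-to-end validation runs 5 oocytes × 2 movies per condition at
128 × 128 px and 100 frames — large enough for ~900 accepted encoded
traces and ~250 mock traces, with per-criterion statistical bands chosen
accordingly (Poisson/binomial standard errors, total-variation ≤ 0.1).
The generator emulates sparse diffraction-limited spots, stepwise
bleaching, planar background and EMCCD-like noise; it does not model
evanescent-field depth, polarization, the EM gain cascade, dark-state
recovery, stage drift, or focal drift. Passing these tests therefore
demonstrates correctness of the analysis chain under the stated imaging
model, not robustness to every artefact of real oocyte data.
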