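# Methods

## The measurement chain

An OCT C-scan is a stack of B-scans with axis order (b-scan, lateral,
depth); a single lateral position's depth profile is an A-scan. The
package analyzes **averaged A-scans**: per B-scan, unusable columns are
dropped (explicit `ExclusionMask` intervals and/or the automatic flagger),
each surviving column's tissue surface is detected on the raw signal, the
columns are shifted to a common surface origin, truncated to the shortest
aligned length and averaged, and the average is then noise-filtered with a
discrete Gaussian (9 taps, σ = 1.5, reflect padding). Alignment precedes
averaging because averaging tilted columns unaligned smears the very
extrema the landmark rule needs; filtering follows alignment because
smoothing spreads the surface ramp a few samples into the air gap and
would degrade surface localization to worse than one pitch.

Surface detection estimates the air floor from the lower half of the
first 10 samples (robust to the ramp intruding when the air gap is short),
sets the threshold at floor mean + 5 floor SD plus 1% of the floor-to-peak
range (so the rule is defined in the noiseless limit where the SD is
exactly zero), and takes the first index that stays above threshold for 3
consecutive samples (guards against isolated speckle spikes). The
detector therefore needs a leading air segment of at least ~10 samples;
profiles already marked surface-origin return index 0, which makes
`remove_air` idempotent.

## Landmarks and thicknesses

On a surface-origin averaged profile the first prominent maximum lies in
the stratum corneum, the first prominent minimum after it is the
stratum-corneum / viable-epidermis boundary, and the next prominent
maximum is the dermis onset. Prominence is 2% of the profile maximum —
small enough to keep anatomical extrema, large enough to reject the
micro-extrema speckle leaves even after averaging; it is configurable.
Thicknesses are index differences × axial pitch; dividing by the tissue
refractive index (default 1.4, configurable) converts the device's
in-air optical depth to physical depth, and reports state which
convention is in use (the CSV outputs use physical depth).

Quantization: each detected boundary lies within one pitch of the true
(continuous) boundary depth. The stratum-corneum thickness involves one
quantized boundary (the surface is index 0 by construction) and is
therefore accurate to one pitch; the epidermis thickness subtracts two
quantized boundaries, so its worst case is two pitches. The test suite
asserts exactly this decomposition on noiseless phantoms.

## Extinction fitting

The dermal decay is fit as `I(z) = I0·exp(−μz) + B` by trust-region
nonlinear least squares over a depth window measured from the surface,
with z in cm so μ is in cm⁻¹ (consistent with the ~50–100 cm⁻¹ range of
skin at 930 nm). Defaults are the papillary (80–180 µm) and reticular
(180–400 µm) windows; a single 120–400 µm window is available by
configuration. No window starting beyond ~400 µm is useful: the signal is
then too close to the noise floor. Initialization: B₀ = window minimum,
μ₀ and I0₀ from a log-linear regression of I − B₀; parameter tolerance
1e−12; bounds I0 ≥ 0, μ ≥ 0, and 0 ≤ B ≤ min over the *whole* profile.

The upper bound on B is the load-bearing numerical choice. B is an
additive detector floor, so it cannot exceed any observed intensity; the
deep tail of a profile, where the signal has decayed into the floor, pins
it. Without the bound, μ and B trade off almost freely over a 100-µm
window (μ·Δz ≈ 0.5 for lymphedematous skin) and the per-scan estimator
develops a heavy right tail under speckle: at CV 0.2 with 100-column
averaging the ensemble-mean bias reaches +7 to +17% for μ ≤ 57 cm⁻¹. With
the bound, the recovery experiments show |bias| ≤ ~2% for μ ∈ [40, 120]
cm⁻¹ in both windows (the small negative residual comes from noise minima
dipping slightly below the true floor). Fits that do not converge or end
on the μ = 0 bound are flagged, excluded from group summaries, and counted.

Normalization to the profile maximum is applied before fitting (and
before CPF) purely for numerical hygiene and comparability: μ and every
downstream statistic are invariant to a global intensity scale, and the
tests assert this.

`block_average` (centered running mean, edge-truncated, default 100
points) is provided as a documented smoothing primitive: on a pure
exponential a fully interior window multiplies the curve by the constant
sinh(μT/2)/(μT/2) — leaving μ untouched — but near the profile start, or
wherever the epidermis hump enters the window, it distorts the shape
badly (a 231-µm window biases an 80–180 µm fit by tens of percent). The
recovery experiments therefore use lateral (column) averaging, which is
how averaged A-scans arise in the first place, as their noise-reduction
step; depth-wise block averaging is safe only for windows far from
structure and edges.

## Curve proximity factor

`S = 1 − Σ|Xᵢ−Yᵢ| / (½Σ(Xᵢ+Yᵢ))` on max-normalized, surface-aligned,
equal-length profiles (normalization configurable off). S is symmetric,
bounded in [−1, 1], 1 iff the curves are identical, and equals
1 − 2·Bray–Curtis; the tests cross-check against an independent
Bray–Curtis implementation. Group summaries form **all cross pairs**
between a group and the reference group (the pairing design is a package
choice; nothing in the definition dictates one), and the significance
star compares the cross-pair S distribution against the within-reference
pair distribution by Mann–Whitney — "less similar to healthy than healthy
is to itself".

## Group statistics

Mann–Whitney is two-sided, exact for combined n ≤ 20 without ties,
otherwise the tie-corrected normal approximation; the exact branch is
verified against full permutation enumeration for all sample-size pairs
with combined n ≤ 10. Quartiles use linear interpolation; whiskers sit on
the most extreme points within 1.5 IQR. Limb volume stacks two truncated
cones from circumference points 1, 3 and 5 (radius C/2π, segment height
1 cm from the 0.5-cm point spacing); points 2 and 4 are carried in the
type but unused by the two-segment scheme.

## Classification

Features are the air-removed, window-3 median-filtered, max-normalized
profile over the first 400 µm, linearly resampled to 200 bins. Per-feature
standardization lives inside the scikit-learn pipeline so its statistics
come from training profiles only. Splits are drawn at subject level
(train fraction 0.8, 3 repeats, resampling any draw that leaves a class
absent from either side); scans of one subject are strongly correlated,
so profile-level splits would leak. SVM hyperparameters are the standard
untuned defaults C = 1, γ = `scale` (1 / (n_features · feature variance)).
Accuracy is correct predictions / total predictions per repeat, reported
as mean ± SD over repeats; a repeat whose test side degenerates to one
class is flagged and excluded from the summary.

## The phantom

The synthetic A-scan is the minimal piecewise profile carrying the
information the analysis uses: air floor → linear ramp to the
stratum-corneum peak (at 30% of the SC thickness) → linear descent to the
boundary valley → linear rise to the dermis peak → exponential decay
exp(−μ·z) from dermis onset, plus a constant baseline everywhere.
Straight segments between landmarks are a deliberate non-commitment:
only extrema positions/intensities and the decay rate matter downstream.
Speckle is i.i.d. multiplicative gamma noise with mean 1 and shape 1/CV²
(default CV 0.2) — the intensity character of fully developed speckle
without a coherent model. Defaults: 2.31 µm axial pitch (2.9 mm over 1253
samples, in air), dermis peak intensity 1, SC peak 0.9, valley 0.55,
baseline 0.03, air gap 60 µm. Group factories place the healthy dermis at
78.912 cm⁻¹ and the two lymphedema stages at 57.282 / 52.221 cm⁻¹ with SC
thickening (20 → 26 → 30 µm) and epidermis thinning (50 → 42 → 36 µm),
matching the contrasts reported for the rat hind-limb model. Cohorts draw
per-subject parameters from Gaussians around the group means
(between-subject SDs ~8 cm⁻¹ in μ, a few µm in thicknesses), resampling —
never truncating — draws that violate positivity/ordering constraints so
the accepted distribution stays unbiased near bounds. Each stored profile
is the lateral mean of 100 speckled columns, the noise level at which all
recovery guarantees are stated.

What the phantom does **not** emulate: coherent speckle correlation
(axial or lateral), the confocal point-spread and sensitivity roll-off of
a real spectrometer, curved or rough layer boundaries, sub-surface
vasculature, and multiple scattering. Passing recovery tests therefore
show the estimators are unbiased and well-conditioned under realistic
noise magnitude and layer geometry — not that every device artifact is
handled; on real volumes the artifact-exclusion step carries that weight.

## Problem sizes

Recovery experiments use 200 averaged scans of 100 columns per condition;
thickness Monte-Carlo uses 60 scans; the classification benchmark uses 15
subjects/group × 10 scans; the permutation null uses 60 relabelings of a
20-subject null cohort. These sizes put Monte-Carlo error comfortably
below the tolerances being asserted (e.g. SE of the recovered-μ mean
≈ 0.15 cm⁻¹ against a 3% ≈ 1.6–3 cm⁻¹ band) while the full suite runs in
well under a minute.

## Known limitations

* The extinction model is single-layer within a window; no depth-resolved
  per-pixel attenuation map is produced.
* Profiles with air gaps shorter than ~10 samples violate the surface
  detector's floor-estimation assumption.
* CPF is computed on intensity profiles; applying it to extinction-vs-
  depth curves instead is possible by feeding those curves in, but no
  convenience wrapper is provided.
* The automatic column flagger is a two-rule proxy (surface deviation
  > 20 samples; sub-surface mean < 50% of the column median) for what is,
  on real data, a judgment call; explicit masks take precedence.
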