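# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the package, in the spirit of a methods appendix.

## Force-curve model and generator

A simulated approach/retract cycle lives on a piezo axis z that increases
away from the surface, with the contact point at z₀ = 5 nm and a retract
travel of 95 nm sampled at Δz = v/f_s = 400 nm s⁻¹ / 2000 Hz = 0.2 nm.
Force is signed as cantilever tension (tether pull positive, hard-contact
repulsion negative). Each attached tether contributes a Marko–Siggia
worm-like-chain branch; because the cantilever deflects toward the surface
under tension, the chain extension at piezo position z satisfies the
load-line equation x = (z − z₀) − F(x)/k, which the generator solves
parametrically in x and interpolates onto the grid. Rupture is instantaneous:
the force returns to baseline within one sample. The exact rupture position
is inserted into the (strictly monotone, then non-uniform) z grid so that the
final pre-rupture sample reads the rupture force exactly; this makes
noiseless round trips bit-faithful and mirrors a force-triggered detachment
at a sampling instant.

Tether attachment per approach is Poisson with rate λ (default 0.155, chosen
so the expected yield 1 − e^(−λ) ≈ 14.3 %, the reported control value).
Rupture forces are i.i.d. draws from a two-component Gaussian mixture.
Component means are the published values (66/132 pN control, 83/164 pN with
copper). The weights (0.5 control, 0.35 copper — the first peak loses weight
under copper) and component SDs (20 and 30 pN) are fixture constants chosen
to produce overlapping two-peak histograms of the published appearance; they
are not measured quantities, and several statistical conclusions below depend
on them. Contour lengths are Gaussian (mean 35 nm, SD 5 nm), representing
PEG-3400 plus peptide with linker-length inhomogeneity; draws that are
non-positive or whose rupture would fall outside the retract range are
resampled. Persistence length is fixed at 0.38 nm (a typical
polypeptide/PEG-scale value). Baseline imperfections are a linear tilt
(default 0.02 pN/nm) plus white Gaussian force noise (default 3 pN).
Deliberately not modeled: 1/f noise, piezo hysteresis, hydrodynamic drag,
loading-rate dependence of the rupture force (the experiment used a single
400 nm/s speed), and surface adhesion on the approach.

## Calibration

The thermal series generator produces stationary white Gaussian deflection
with variance k_B·T/k — sufficient statistics for a variance-based
calibration. The spring-constant fit is therefore the equipartition estimator
k = k_B·T / Var(deflection) in the time domain rather than a fit of a
harmonic-oscillator line shape to the power spectrum; for white synthetic
data the two coincide, and the module boundary allows a PSD fit to be
swapped in for real spectra. k_B = 1.380649 × 10⁻² pN·nm/K and the default
temperature is 298 K, so k_B·T ≈ 4.11 pN·nm. Sensitivity is the inverted
absolute least-squares slope of the hard-contact segment (deflection signal
vs z), and force conversion is F = signal × sensitivity × k.

## Event detection and WLC fitting

Baseline: a line fitted to the far-from-surface quarter of each segment is
subtracted. Contact point: starting from the deepest (most repulsive)
smoothed approach sample, the algorithm walks outward until the repulsion has
released to 5 % of its depth, then intersects a line fitted to the contact
region with the local free-level baseline; starting at the contact side makes
the search immune to baseline noise outliers, and using the local level
cancels residual baseline-extrapolation drift. Under 2 pN noise the contact
point is recovered to well under one sample.

Detection: a rupture is a force drop ≥ 5× the noise SD completed within ≤ 3
samples, preceded by ≥ 10 samples of monotonically increasing tension
(evaluated on a 5-sample moving average with a noise-scaled slack, ending a
filter half-width before the candidate so the post-rupture drop cannot
contaminate the test). Candidates within the drop span merge; the last
candidate of a cluster — the final pre-rupture sample — represents the event.
The 5σ threshold and the monotone-rise precondition were chosen to hold the
false-positive rate on event-free noisy baselines below 5 % (asserted in the
tests at noise SD 5 pN). Events closer than roughly the rise window
(~13 samples) are not separable by construction of this rule.

WLC fitting inside the per-curve pipeline is performed against piezo
position: the model F = WLC(z − z₀ − F/k) is evaluated via its parametric
load-line form and least-squares fitted over (L_p, L_c) with three
contour-length restarts. Fitting in piezo coordinates keeps the measurement
noise out of the abscissa — applying the tip–sample-separation correction
with the *measured* noisy force (the textbook formula, also exposed as
`fit_wlc` for extension/force segments) injects force noise into the
extension axis, which near the steep end of the curve acts like an extra
~8 pN of effective force noise and attenuates the fitted stiffness. The
reported rupture force is the fitted model's load-line value at the rupture
sample when it agrees with the raw drop magnitude (within 5× noise SD), and
the raw drop otherwise — on superposed multi-tether stretches the single
chain fit is poor, but the drop at one tether's rupture still equals that
tether's tension because the others are continuous through it. Measured
accuracy on single-tether curves: < 0.01 pN noiseless, ~1.3 pN mean absolute
error at 5 pN noise.

Specificity: an event is specific when its rupture distance lies in the
10–60 nm PEG-tether window, the WLC residual is below 10 pN, and the rupture
*extension* (distance minus the cantilever deflection F/k) stays below the
fitted contour length. The deflection correction in that last bound matters:
comparing the raw piezo distance against L_c systematically rejects
high-force, short-tether events (measured: the > 110 pN population dropped
from 31 % to 16 % of the sample before the correction).

## Rupture-force statistics

Yield is 100 × (curves with ≥ 1 specific event)/(curves). The
multiple-tether correction assumes Poisson attachment: λ = −ln(1 − yield)
and p = [1 − e^(−λ)(1+λ)]/(1 − e^(−λ)) is the probability that a curve
showing any event had ≥ 2 tethers; exactly ⌊p·n⌋ of the n highest retained
forces are discarded (floor, since no rounding rule is standard). p(0.143) ≈
0.075 and p(0.221) ≈ 0.12, consistent with the published working point. The
generator's Poisson attachment law was chosen to match this correction
formula exactly, so the correction is self-consistent within the package.

The two-Gaussian fit operates on histogram counts (default 10 pN bins) with
Levenberg–Marquardt, multi-started from the two most separated smoothed
histogram modes, a quartile-based guess, and perturbed restarts under a fixed
sub-seed. Solutions pass a sanity screen — positive amplitudes, widths
between a third of a bin and half the span, means inside the data range,
separation ≥ 1.5 bins, each component ≥ 5 % of the area — with a bounded
trust-region rescue when no unconstrained solution qualifies, and a
`degenerate` flag when even that fails (single-mode data). Residuals are
Poisson-weighted (σ_bin = √max(count, 1)) by default: on sparse histograms
the *unweighted* SSR optimum is frequently a non-peak solution (one narrow
spike plus one very wide component soaking the inter-peak shoulder);
measured over 30 replicates of the 2000-draw control recovery, Poisson
weighting reduces the worst-case upper-peak error from 21 pN to 7 pN.
Plain least squares remains available (`weighted=False`). Peak SEs use the
effective-counts rule SE_i = σ_i/√(N·f_i), which assumes well-separated
components and understates the true uncertainty when they overlap as
strongly as the default fixtures do. The condition mean force is computed
after the discard step (the alternative ordering is not distinguishable from
the published description) and is flagged as such in the report.

A consequence worth stating plainly: with component SDs 20/30 pN and equal
weights, a single 1000-curve experiment (~140 events) carries a
maximum-likelihood uncertainty of roughly 5 pN on the upper peak position.
End-to-end recovery to better than that is a coin flip per realization, and
the corresponding acceptance-style check is expected to fail for some seeds
— the tests document one such realization rather than masking it. At 2000
directly drawn events the peaks are recovered to a few pN reliably.

## AFM image quantification

The generator renders spherical-cap oligomers (paraboloid profile, apex
snapped to the pixel grid so a noiseless cap's maximum equals its nominal
height), half-cylinder fibril ridges, and irregular amorphous blobs
(harmonically modulated radius, rounded dome profile) on a tilted plane
(default 0.5 nm/µm) with white pixel noise (default 0.3 nm), at 10 nm/pixel
over 5×5 µm. Features are placed by occupancy-mask rejection so that long
ridges can coexist without bounding-circle over-rejection.

Flattening fits a background plane by least squares on pixels below
median + 1 SD (excluding features), then refits on background pixels within
a robust 3σ band so noise truncation does not bias the plane. Segmentation
thresholds at max(3× robust background SD, 0.5 nm) and drops components
under 4 pixels. Heights are read per feature as: the maximum of a 3×3-median
despeckled crop for compact features (a raw max rides the upper tail of the
pixel noise — for a large flat-topped blob the bias is ~2.8σ ≈ +0.85 nm,
well outside tolerance; the median filter removes it at a small attenuation
cost), and the crest mean (mean of per-transect maxima along the major axis)
for fibrils. Lengths use the maximum Feret diameter (the moment-based major
axis overshoots rod-like shapes by ~15 %); widths use the moment-based minor
axis. Classification is a fixed, total rule kept in configuration:
fibril ⇔ aspect ≥ 5 and length ≥ 100 nm; amorphous ⇔ max height ≥ 6 nm,
compact, and area ≥ 10⁴ nm²; oligomer otherwise. The thresholds separate
the three described morphologies (≈3 nm caps, 4.5–7.2 nm ridges, ≈9.3 nm
blobs) and are not derived from data. "Mean height" per class is the mean of
per-feature representative heights (max for caps/blobs, crest mean for
fibrils); whether the published per-class means were computed per-feature or
per-pixel is not stated, and the per-feature reading is used here.

What passing the image tests shows — and does not: recovery within 0.5 nm is
demonstrated for well-separated synthetic features on a planar background
with white noise. Real topographs add tip convolution, scanner bow, line
noise and touching aggregates, none of which are modeled; no tip
deconvolution or volume estimation is attempted.

## Orchestration and reproducibility

The pipeline expands one master seed into fixed per-stage sub-seeds
(curves: +101 with a per-condition stride, images: +301), so stages can be
rerun independently and the whole report bundle is byte-reproducible for a
given configuration. All generators accept explicit seeds or Generator
instances; the test suite and the acceptance script pin every random stream.
Problem sizes used throughout (2000 draws for mixture recovery, 1000 curves
per simulated experiment, 500×500-pixel images) were chosen as realistic
single-experiment scales for this kind of measurement.
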