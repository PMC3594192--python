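# smforce

Analysis toolkit for single-molecule atomic force spectroscopy (AFS) of
peptide–peptide unbinding and for AFM topography of the resulting aggregates.
The motivating system is amyloid-β (1–42) dimerization with and without Cu²⁺:
each approach/retract cycle of an AFM cantilever can capture one Aβ–Aβ bond
through PEG tethers, and the force at which the bond ruptures — read from the
retract force–distance curve — is collected into histograms whose two Gaussian
peaks shift upward when copper bridges the peptides. The companion AFM images
track how the same chemistry changes aggregate morphology (oligomers → fibrils
without copper; large amorphous aggregates with copper).

The package is a library first (`import smforce`), with short narrative
scripts in `examples/` and a thin `smforce` command-line wrapper. Because no
public raw data exist for this kind of experiment, the package ships a
synthetic-data module that generates force curves, thermal calibration series
and topographs with known ground truth; every analysis stage is validated by
recovering that truth.

## What it computes

**Calibration.** Optical-lever sensitivity from the hard-contact slope of a
force–displacement plot, and the cantilever spring constant by the thermal-tune
(equipartition) route, k = k_B·T / Var(deflection). Photodiode signal converts
to force as F = signal × sensitivity × k.

**Rupture-event extraction.** Retract curves are baseline-corrected, the
contact point z₀ located on the approach, and rupture candidates detected as
force drops ≥ 5× the noise SD completed within 3 samples after a sustained
rise. Each tether stretch is fitted with the Marko–Siggia worm-like chain,

    F(x) = (k_B T / L_p) · [ 1/(4 (1 − x/L_c)²) − 1/4 + x/L_c ],

with persistence length L_p and contour length L_c free, against piezo
position (the tip–sample separation is x = z − z₀ − F/k). Events are flagged
*specific* when the rupture distance falls in the PEG-tether window
(10–60 nm) and the fit is good.

**Rupture-force statistics.** The experimental yield (percent of curves with
a specific event) feeds a Poisson attachment model: λ = −ln(1 − yield) and
p = [1 − e^(−λ)(1+λ)] / (1 − e^(−λ)), the probability that a recorded event
was ≥ 2 tethers rupturing at once; the ⌊p·n⌋ highest forces are discarded.
The retained forces are histogrammed (10 pN bins) and fitted with a sum of
two Gaussians by Levenberg–Marquardt least squares; peak standard errors use
effective counts, SE_i = σ_i / √(N·f_i) with f_i the component's area
fraction. Conditions are compared via peak shifts with quadrature SEs.

**AFM morphometry.** Topographs are plane-flattened (feature-excluding
background fit), segmented by height threshold, and each feature measured
(max/crest height, length, width, aspect ratio) and classified as oligomer,
fibril (elongated, ≥ 100 nm) or amorphous aggregate (tall and large), giving
per-condition, per-incubation-time class counts and mean heights.

## Worked example

```bash
python examples/01_mixture_recovery.py
```

```
control: generating peaks 66/132 pN -> fitted 66.2±0.6 / 132.6±0.9 pN (area fraction of peak 1: 0.52)
copper: generating peaks 83/164 pN -> fitted 84.7±0.7 / 163.5±0.8 pN (area fraction of peak 1: 0.35)
```

2000 rupture forces are drawn from each condition's two-component mixture and
the histogram fit recovers the generating peak positions within a couple of
standard errors; the copper condition carries less area in its first peak,
the signature of events shifting toward the stronger (copper-bridged)
complex. The multiple-tether arithmetic:

```bash
python examples/03_multiple_tether_correction.py
```

```
yield 14.3 % -> attachment rate λ = 0.154, P(≥2 tethers | event) = 0.075
yield 22.1 % -> attachment rate λ = 0.250, P(≥2 tethers | event) = 0.120
```

and the imaging side:

```bash
python examples/04_afm_timecourse.py
```

```
condition time  n_oligomer  mean_height_oligomer_nm  n_fibril  mean_height_fibril_nm  n_amorphous  mean_height_amorphous_nm
  control  1 h          20                     3.01         0                    NaN            0                       NaN
  control 24 h           5                     2.98         5                   7.05            0                       NaN
   copper  1 h          20                     3.00         0                    NaN            0                       NaN
   copper 24 h           6                     3.10         0                    NaN            8                      9.25
```

Planted ~3.13 nm oligomer caps, 7.2 nm fibril ridges and 9.3 nm amorphous
blobs are recovered within ~0.1 nm, and the copper end point contains no
fibril-class features. `examples/02_force_curve_roundtrip.py` shows a single
curve analyzed end to end, and `examples/05_full_pipeline.py` (or
`smforce run-all --config examples/config.yaml --out report/`) runs the whole
simulate → analyze → statistics → compare → image chain into a report bundle.
Note that a single 1000-curve experiment yields only ~140 specific events, so
per-experiment peak positions carry several pN of statistical uncertainty.

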