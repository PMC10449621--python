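# Methods

This note documents the models behind `guvquant`, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical conventions that make results reproducible.

## Synthetic microscopy fields

`synthetic_microscopy` renders two-channel (TXR reference dye / GFP
reporter) epifluorescence fields of GUV synthetic cells with exact
per-vesicle ground truth.

**Diameters.** Vesicle diameters follow a *truncated log-normal* on
[3, 20] um whose underlying parameters are solved numerically (closed-form
truncated moments + root finding) so that the truncated distribution has
mean 6.5 um and s.d. 2.3 um — the population statistics of emulsion
phase-transfer GUV preparations. Sampling uses the inverse CDF restricted
to the truncation interval, so draws are deterministic under a seeded
generator and never leave the bounds.

**Intensities.** Every vesicle's TXR lumen intensity is log-normal
(median 100 gray units, sigma_log 0.25, arbitrary units). Reporter "on"
intensities are log-normal with median 25 and sigma_log 0.75, which puts
the 5th-95th percentile span at ~11.8x — matching populations whose
expression spans an order of magnitude. Non-expressing vesicles sit at a
basal lumen level of 1.2 gray units, a few-fold above zero as observed for
no-template controls. Each vesicle is "on" with probability
`expressing_fraction` (default 0.9); a binary photomask additionally forces
vesicles centered outside it off.

**Rendering.** Disks are filled (the dye and reporter occupy the lumen) and
anti-aliased with a half-pixel linear coverage ramp symmetric about the
true radius (coverage 0.5 exactly at r), a close approximation to exact
pixel-area coverage that makes sub-pixel diameter recovery meaningful.
Channel background (TXR 5, GFP 2) and additive Gaussian noise (default
sd = 2, i.e. 2 % of the TXR median; optional Poisson) are applied last, and
rasters are clipped at 0. Centers are rejection-sampled with disks fully
in-field and center separation > 0.9x the sum of radii, keeping objects
resolvable; an unsatisfiable density raises an error naming the achievable
count.

**Pixel-size regimes.** The generator defaults to 0.65 um/px (a ~x10
objective regime used for wide patterning fields) and offers 0.13 um/px
(~x100, the single-vesicle quantification regime). Camera pitch and bit
depth are conventions, not measured values; TIFF output is 16-bit.

**Known rim bias.** Averaging over the ROI "pixel centers inside the
circle" underestimates the lumen intensity by roughly `0.25/r` (r in px)
because the ROI includes the outer half of the anti-aliased rim.
Quantitative intensity checks therefore run in the 0.13 um/px regime
(r >= 11.5 px, bias <= 2.2 %); at 0.65 um/px the bias reaches ~11 % for the
smallest vesicles. Ratio-based statistics (expressing threshold, contrast)
are insensitive to this because it cancels between populations.

**Not emulated:** optics (no PSF, diffraction or defocus), z-structure,
brightfield, vesicle motion or deformation, membrane/lumen sub-structure,
spectral bleed-through, illumination shading. Passing tests demonstrate
correctness of the *analysis chain* on geometrically ideal, noise-perturbed
disks; they do not certify performance on aberrated or crowded real
micrographs.

## Plate assays

`synthetic_assays` emulates 96-well receiver-cell assays. Fluorescence is
the four-parameter Hill curve evaluated at the well concentration times a
multiplicative log-normal factor with unit mean and coefficient of
variation `noise_cv` (default 10 %, a typical plate-reader + biological
replicate scale; the sources report only mean +- s.d. of n = 3). OD600 is
carried as an inert column (0.05 +- 5 % Gaussian), mirroring assays that
record optical density but fit raw fluorescence. Zero-ligand wells are
included by default and evaluate to the basal output b.

The default concentration series is a ten-fold serial dilution from
63.2 uM to 632 pM (six points). A configurable step supports the half-log
(sqrt(10), 11-point) series with the same endpoints; dose-response
*fitting* experiments in the acceptance suite use the half-log series
because the ten-fold series leaves a single concentration inside the
transition around EC50 = 1 nM, which is not enough to constrain (EC50, h)
jointly under noise — EC50 estimates at the reported +-11 % precision
require denser transition sampling.

## Hill model, fitting and inversion

The response is the standard four-parameter logistic in log concentration,

    GFP(X) = b + (a - b) / (1 + 10^(h (log10 EC50 - log10 X)))
           = b + (a - b) / (1 + (EC50 / X)^h),       GFP(0) = b,

with midpoint GFP(EC50) = (a+b)/2 and saturation at a. Fits are bounded
least squares per replicate on (a, b, log10 EC50, h), initialized at
b0 = min y, a0 = max y, EC50_0 = geometric mean of the positive
concentrations, h0 = 1, with EC50 bounded to [min conc/100, max conc x 100]
and h to (0, 10]. A small multi-start (EC50 at the series ends and center x
h in {0.7, 1, 2}) removes shallow-h/runaway-EC50 local minima; the lowest
residual wins. Zero-concentration wells enter via the X -> 0 limit.
Replicate fits are summarized as mean +- sample s.d. per parameter; the
"mean curve" used for inversion takes arithmetic means.

The inverse `X = EC50 ((a-b)/(GFP-b) - 1)^(-1/h)` is applied only to wells
strictly inside the dynamic range with a 5 % margin: wells within 5 % of a
are flagged *saturated*, within 5 % of b *below range*, and excluded (the
inverse is ill-conditioned near the asymptotes, where small fluorescence
errors map to unbounded concentration errors). Per-well stock estimates
(assay concentration x dilution factor) are pooled by geometric mean, with
a geometric s.d. as dispersion — concentrations are log-scale quantities.
If no well is usable, the estimator raises an error carrying the flag
counts rather than returning a number.

Yield conversion: a sample of `sample_ul` microliters at `conc_nM` contains
`conc_nM x 1e-3 x sample_ul` pmol; dividing by the inner-solution volume
gives pmol per ul of inner solution (1 uM corresponds to 1 pmol/ul at equal
volumes).

## Detection and quantification

Normalization applies one affine map per (experiment, channel), anchoring
the 1st and 99.9th percentiles of the pooled pixel distribution to [0, 1];
the high percentile is robust to hot pixels, and because percentiles are
affine-equivariant the operation is exactly idempotent and preserves
relative intensities across images. Background is the arithmetic mean of a
user-chosen vesicle-free region (a warning, not an error, if it overlaps a
detection — region choice mirrors a manual selection).

Detection runs on the normalized TXR channel: Canny edges (sigma 1.2,
thresholds 0.05/0.12 in normalized units), circular Hough accumulation over
a 1 px radius grid (default search 0.75-12.5 um radius), per-radius peak
extraction above a sensitivity of 0.35 (normalized votes), sub-pixel center
refinement by the 3x3 accumulator centroid, radius refinement first by
parabolic interpolation across the radius axis and then by the half-height
crossing of the radial intensity profile (0.5 px bins, median per bin) —
the anti-aliased rim crosses the lumen/background midpoint at the true
radius. Candidates whose radial profile shows lumen-minus-background
contrast below 0.05 are rejected; this suppresses the spurious peaks that
the perimeter-normalized accumulator produces at the smallest radii.
Finally, overlapping detections (center distance < 0.8x sum of radii) keep
only the higher score. At default SNR this yields recall 1.0, precision
>= 0.98 and median diameter error ~0.06 px on 100-vesicle fields.

Measurement: ROI = pixels whose centers lie inside the detected circle
(simple, reproducible, matching manual circular-ROI practice); per-channel
mean; corrected mean subtracts the scalar background (negative values are
preserved, not clipped). `diameter_um = 2 x radius_px x pixel size`. ROIs
under 5 px are flagged and excluded from population statistics but kept in
the records for auditability.

## Population statistics and classification

The expressing threshold is the no-template control population's sample
mean + 3 sample s.d. (n-1 denominator) of per-vesicle background-corrected
reporter means. The comparison is strict (>): a population identical to its
control yields fraction 0. Quantiles use the linear-interpolation
convention. Fold activation is ON/OFF; a variant's fold decomposes as
reference fold x OFF-state decrease x ON-state increase (commutative in the
change factors).

## Patterning metrics

Masks are binary rasters registered to the image grid (registration itself
is out of scope). Features are 4-connected components; a feature's width is
twice its maximum distance-transform value times the pixel size (the
largest inscribed disk; a 1-px line has width 2 px by this convention, and
odd-sided squares round up by one pixel). Fidelity is the fraction of
expressing vesicles centered inside the mask; contrast is the ratio of mean
corrected reporter intensity inside vs outside (reported as a flag when no
outside population exists). A feature is *resolved* when it contains at
least `k` expressing vesicles and its local contrast reaches `c_min`
(defaults k = 3, c_min = 2; both configurable — "resolved" is qualitative
in the source setting, so the rule is declared and tested against its own
definition).

For the stripe-width resolution experiment the suite uses one centered
full-height stripe per width in {400, 200, 100, 50} um on a 1200x1600 px
field (0.65 um/px) with 500 vesicles and k = 30: expected expressing counts
per stripe are ~{156, 78, 39, 19.5}, so the count criterion separates
100 um (probability ~0.93 of >= 30) from 50 um (~0.01) against Poisson
fluctuations, producing a resolved/unresolved transition at ~100 um.
With k = 3 and areas differing only 2x between adjacent widths, no density
makes the transition statistically sharp; k is therefore matched to the
density-area product of the experiment.

## Pipeline and reproducibility

All randomness flows from `numpy.random.default_rng(seed)`; every simulated
object is bit-reproducible under a fixed seed. The pipeline fans one global
seed out as seed + stage index, exchanges only flat files (16-bit TIFF, CSV,
JSON), and writes a manifest with a SHA-256 checksum per artifact plus a
hash of the semantic configuration (seed, stages, parameters — not output
paths). Re-running with the same configuration skips stages whose recorded
outputs are unchanged; determinism is checked by manifest checksum
equality.

## Problem sizes in the test and acceptance runs

Detection quality: one 1024x1024 field, 100 vesicles. Quantification
recovery: one 2048x2048 field at 0.13 um/px, 200 vesicles. Classifier
calibration: 2048x2048, 500 vesicles (truth fraction 0.90). Patterning:
five 1200x1600 fields, 500 vesicles each. Hill Monte-Carlo: 100 simulated
plates, 3 replicates each, 10 % CV. These sizes give tight Monte-Carlo
tolerances (binomial s.e. of the 500-vesicle fraction ~0.013) while keeping
a full run on one CPU to a couple of minutes.

## Known limitations

* Absolute intensities are instrument-arbitrary ("gray units"); only
  relative and population structure is meaningful.
* The detector assumes approximately circular, mostly non-overlapping,
  fully-in-frame vesicles; heavily fused or clipped objects are outside its
  contract.
* The titer estimator assumes the assayed sample behaves identically to the
  calibration ligand (no matrix effects between CFPS mixtures and buffer).
* The OD600 column is simulated but unused, matching the apparent practice
  of fitting raw fluorescence; no growth-normalization model is provided.
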