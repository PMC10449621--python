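# guvquant

Quantitative analysis for synthetic-cell (giant unilamellar vesicle, GUV)
experiments in which gene expression is switched on with light and read out
by fluorescence: per-vesicle image quantification, expressing-fraction
classification, Hill dose-response characterization of quorum-sensing
receiver cells, inverse quantification of biosynthetic acyl-homoserine
lactone (AHSL) titers, and photomask pattern-fidelity scoring.

The package is aimed at synthetic-biology / bottom-up synthetic-cell labs
that image polydisperse GUV populations (3-20 um diameter) in a reference
dye channel (TXR; every vesicle carries a Texas-Red dextran) and a reporter
channel (GFP), and that calibrate receiver-cell reporter assays in 96-well
plates. Because such studies rarely deposit raw instrument data, the
package ships first-class synthetic-data generators with exact per-vesicle
and per-well ground truth, so every stage of the analysis is testable.

## What it computes

**Image side.** Images are brightness-normalized per experiment (one shared
affine map per channel anchored at robust percentiles), a scalar background
is taken from a vesicle-free region, and vesicles are found by circular
Hough detection on the TXR channel (Canny edges, 1 px radius grid, sub-pixel
center/radius refinement, overlap suppression). Each detection yields a
diameter (um) and background-corrected mean intensity per channel. A vesicle
counts as *expressing* when its corrected reporter mean exceeds the
no-template control population's mean + 3 s.d.

**Plate side.** Receiver-cell fluorescence follows the four-parameter Hill
curve

    GFP(X) = b + (a - b) / (1 + (EC50 / X)^h)

with `a` maximal output, `b` basal output, `EC50` the half-maximal ligand
concentration and `h` the Hill coefficient. Curves are fitted per replicate
by bounded least squares and summarized as mean +- s.d. across replicates.
The closed-form inverse `X = EC50 ((a-b)/(GFP-b) - 1)^(-1/h)` back-calculates
unknown AHSL stock concentrations from wells at known dilution factors
(geometric-mean pooling; wells within 5% of either asymptote are flagged
saturated / below range instead of inverted). Concentrations convert to
biosynthetic yields as `pmol/ul inner solution = nM x 1e-3 x sample_ul /
inner_ul`.

**Patterning.** A binary photomask is decomposed into 4-connected features
(width = largest inscribed-disk diameter); expression patterns are scored by
fidelity (fraction of expressing vesicles inside the mask), in/out contrast
and a declared feature-resolution rule (at least `k` expressing vesicles and
local contrast at least `c_min`).

## Worked example

```python
import numpy as np
from guvquant import (SimImageConfig, simulate_field, normalize_experiment,
                      detect_vesicles, estimate_background, quantify_image_set,
                      records_to_dataframe, control_threshold, expressing_fraction,
                      yield_per_inner_solution)
from guvquant.synthetic_microscopy import TXR

# a no-template control field and a 90%-expressing field, 1024x1024 px
control_cfg = SimImageConfig(expressing_fraction=0.0, rng_seed=0)
sample_cfg  = SimImageConfig(expressing_fraction=0.9, rng_seed=1)
control, _ = simulate_field(control_cfg); control.image_id = "control"
sample, truths = simulate_field(sample_cfg); sample.image_id = "sample"

normalized, _ = normalize_experiment([control, sample])
frames = {}
for s in normalized:
    dets = detect_vesicles(s[TXR])
    bg = estimate_background(s, (slice(0, 40), slice(0, 40)))
    frames[s.image_id] = records_to_dataframe(quantify_image_set(s, dets, bg))

thr = control_threshold(frames["control"])
fraction, flags = expressing_fraction(frames["sample"], thr)
print(f"detected {len(frames['sample'])} vesicles, "
      f"expressing fraction {fraction:.3f} "
      f"(truth {np.mean([t.expressing for t in truths]):.3f})")
print(f"yield: {yield_per_inner_solution(458.5, 25.0, 5.0):.4f} pmol/ul")
```

prints

```
detected 101 vesicles, expressing fraction 0.891 (truth 0.890)
yield: 2.2925 pmol/ul
```

i.e. the detector recovers the 100 simulated vesicles (one spurious
detection here), the classifier reproduces the generator's expressing
fraction, and a 25 ul sample at 458.5 nM made from 5 ul of vesicle inner
solution corresponds to ~2.29 pmol of product per microliter of inner
solution.

A command-line interface mirrors the library one-to-one
(`guvquant simulate-images | simulate-assay | detect | quantify | population |
fit-dose-response | quantify-ahsl | yield | pattern-score | run`); `guvquant
run` executes the whole chain with flat CSV/JSON/TIFF handoffs and writes a
checksummed run manifest.

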