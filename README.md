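# clutchmap

Coordinate-level analysis of dSTORM single-molecule localisation maps of cell
nuclei — built for quantifying nanoscale chromatin organisation (nucleosome
clutches and the chromatin aggregates they form) from blink tables, the way it
is done for histone-mark imaging in embryo nuclei.

Super-resolution dSTORM reduces an acquisition to a list of *blinks*: single
fluorophore localisations with frame number, position (nm), photon count and
precision. Starting from such a table and a nucleus outline, `clutchmap`:

1. **filters** blinks on photon count (300–5000), localisation uncertainty
   (≤ 35 nm) and PSF width (≤ 200 nm), and clips them to the nucleus polygon;
2. **homogenises** blink density across samples by keeping only the last *k*
   acquisition frames, with *k* chosen so the retained global density best
   approximates 0.001 blinks/nm² (samples that cannot reach it are flagged
   and excluded);
3. **segments** hierarchically: DBSCAN denoising (ε = 60 nm, min points 10) →
   complete-linkage clustering cut at 160 nm into *nucleosome clutches*
   (≥ 10 blinks, density ≥ 5× global) → chaining of clutches whose blinks come
   within 30 nm into *chromatin aggregates*;
4. **measures** per nucleus: periphery z-scores of blinks, clutch densities
   and proximities (10 nearest neighbours, boundary-to-boundary), and
   blink-count-weighted aggregate diameters, occupied-area fractions and
   densities, with non-convex (alpha-shape) structure boundaries;
5. **computes spatial statistics** with minus-sampling border correction
   against the actual nuclear boundary: the radial distribution function
   g(r), the H-function H(r) = √(K(r)/π) − r, and the empty-space F-function
   with a Monte-Carlo *deviation from randomness* score (10,000 evaluation
   points, 25 reshuffles).

Under complete spatial randomness, g ≡ 1, H ≡ 0, the mean periphery z-score
is 0 and the F-deviation is 0; clustering pushes g and H up at small r and
the F-deviation positive, while regular (mutually repelling) patterns push
the F-deviation negative.

No public localisation data exist for this assay, so the package ships a
first-class synthetic generator (`clutchmap.synthetic`) producing irregular
star-convex nucleus polygons, CSR and perinuclearly biased blink fields,
clutch/aggregate patterns with exact ground-truth labels, and frame-stamped
ThunderSTORM-dialect localisation tables.

## Worked example

```python
import numpy as np
import clutchmap as cm

# an irregular nucleus and a known 20-clutch blink pattern + 10% background
roi = cm.make_nucleus(cm.NucleusShapeSpec(base_radius=2000, irregularity=0.3, seed=1))
spec = cm.ClutchPatternSpec(n_clutches=20, clutch_radius=40, blinks_per_clutch=30,
                            background_fraction=0.1, seed=2)
blinks, truth = cm.sample_clutch_pattern(roi, spec)

seg = cm.segment(blinks)                 # denoise -> clutches -> aggregates
summary = cm.summarise_nucleus(blinks, seg.clutches, seg.aggregates, roi)
centres = np.array([c.centre for c in seg.clutches])
fd = cm.f_deviation(centres, roi, seed=3)
```

prints (via the obvious `print` statements):

```
nucleus area: 1.27e+07 nm^2, blinks: 667
clutches recovered: 20 (generated: 20)
mean clutch radius estimate: 27.5 nm
mean periphery z-score: -0.054
mean clutch density: 1.29e-02 blinks/nm^2
weighted mean aggregate diameter: 55 nm
F-deviation from randomness: -82.5 nm
```

All 20 generated clutches are recovered with their exact memberships. The
radius estimate (27.5 nm) is the equivalent-circle radius of the alpha-shape
boundary, necessarily below the generating disc radius of 40 nm for 30
uniform draws. The *negative* F-deviation is real signal, not error: this
generator mode keeps clutch centres mutually separated so recovery is
unambiguous, and an enforced minimum separation is a regular pattern — its
empty spaces are *smaller* than random. Aggregated patterns
(`aggregation_radius=...`) give increasingly positive deviations.

## Analysis drivers

Numbered scripts under `analysis/` run the full study on synthetic data and
write tables under `results/` (raw simulated localisation tables go under
`scratch/`, which is disposable):

| script | what it does |
| --- | --- |
| `01_simulate_cohort.py` | simulates two groups of 4 nuclei: *dispersed* vs *aggregated* chromatin-like blink patterns |
| `02_run_pipeline.py` | runs the full pipeline per nucleus; per-nucleus and per-group mean ± SEM tables |
| `03_csr_calibration.py` | CSR null calibration of RDF/H/z and the border-correction comparison |
| `04_spatial_contrasts.py` | periphery z-score vs radial bias; F-deviation vs aggregation level |

There is also a CLI for one-off use: `clutchmap simulate ...`,
`clutchmap homogenise ...`, `clutchmap spatstats rdf|h|f ...`,
`clutchmap pipeline run --config config.yaml --out-dir run/`.

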