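# trabkit

Trabecular bone morphometry and ontogenetic cohort statistics.

Trabecular (cancellous) bone remodels rapidly under load, so its
architecture in the articular heads of long bones records how an animal
uses its limbs as it grows. `trabkit` is a reusable pipeline for
quantifying that architecture from 3-D image stacks and analysing it across
an age-structured cohort: it takes oriented voxel volumes through spherical
ROI extraction, Otsu segmentation and purification, computes the standard
morphometric suite — bone volume fraction (BV/TV), degree of anisotropy
(DA), trabecular thickness/spacing/number (TbTh, TbSp, TbN) and the primary
fabric orientation (azimuth/plunge) — and runs the cohort-level statistics:
coefficients of variation, Pearson/partial correlations, PCA, Kruskal–Wallis
with Dunn post-hocs, allometric log-log regression against isometric
expectations, and equal-area orientation projection. A synthetic generator
produces strut-lattice phantoms, whole-bone mocks and five-age-group
cohorts with known ground truth, so the entire pipeline is testable without
any scan data.

It is written for comparative and evolutionary morphologists who work from
µCT-derived TIFF stacks and per-specimen metadata tables, and is equally
usable as a Python library or through its small CLI.

## The core quantities

The fabric tensor comes from the **mean intercept length**: for a test
direction ω, MIL(ω) = L·(BV/TV)/I(ω), where L is the total test-line length
in the ROI sphere and I(ω) the number of marrow→bone crossings. Fitting

&nbsp;&nbsp;&nbsp;&nbsp;1/MIL(**n**)² = **n**ᵀ **M** **n**

over ~512 quasi-uniform directions gives a symmetric positive-definite
**M** whose eigenvectors are the principal trabecular directions and whose
ellipsoid radii rᵢ = 1/√λᵢ define **DA = 1 − r₃/r₁** (0 = isotropic).
TbTh and TbSp are Hildebrand–Rüegsegger local thickness (diameter of the
largest inscribed sphere) of the bone and marrow phases; TbN defaults to
the plate model (BV/TV)/TbTh. Allometry is assessed on log-log slopes of
each metric against estimated log body mass, compared with the isometric
exponents 0 (BV/TV, DA), +1/3 (TbTh, TbSp) and −1/3 (TbN); azimuths are
folded by ||x − 180| − 90| before correlation/ordination so axially
equivalent compass directions pair up. See `docs/methods.md` for the full
model description and numerical conventions.

## Worked example

`examples/01_phantom_morphometry.py` builds a 96³ phantom of radius-4
struts aligned with +Z (target BV/TV 0.30, voxel 30 µm) and measures it:

```
generated 89 struts, achieved BV/TV 0.280 (target 0.3)
BV/TV  0.270   (bone fraction inside the ROI sphere)
DA     0.614   (0 = isotropic, 1 = fully aligned)
TbTh   0.218 mm (mean strut thickness; truth 0.24 mm)
TbSp   0.415 mm (mean marrow spacing)
TbN    1.24 /mm (struts per mm, plate model)
plunge 89.8 deg (90 = vertical primary orientation)
```

The ROI recount matches the generator's ground truth, the fabric's primary
axis is recovered within a fraction of a degree of the generating +Z axis,
and the mean thickness sits within discretization error of the true strut
diameter. The other examples walk the remaining capabilities:
`02_whole_bone_pipeline.py` (landmark orientation → cortex-free sphere →
Otsu → metrics on a noisy whole-bone mock), `03_cohort_statistics.py`
(group tests, allometry and PCA on a simulated 55-specimen cohort — BV/TV
peaking in the 4–12-month group and logBM/plunge/DA co-loading on PC1), and
`04_orientation_projection.py` (ontogenetic reorientation from rim to
center of the equal-area disk).

A thin CLI mirrors the pipeline stages:

```sh
trabkit simulate --kind cohort --seed 7 --out sim/
trabkit analyze  --table sim/cohort.csv --seed 7 --out report/
trabkit simulate --kind whole_bone --seed 7 --out bone/
trabkit measure  --manifest bone/manifest.json --out metrics.csv
```

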