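# mrhotspot

Spatial-correspondence analysis between metabolic and relaxometric "hotspots"
in glioma imaging.

## Scientific problem

High-grade gliomas infiltrate beyond the contrast-enhancing tumor core, and
different quantitative MR modalities see that infiltration differently.
High-resolution **MR spectroscopic imaging (MRSI)** at 7 T yields metabolite
ratio maps — total choline (tCho), glutamine (Gln), glycine (Gly) and
myo-inositol (Ins), each referenced to total N-acetyl-aspartate (tNAA) or
total creatine (tCr) — whose focal elevations mark active tumor metabolism.
**MR fingerprinting (MRF)** at 3 T yields quantitative T1 and T2 relaxation
time maps whose elevations mark microstructural change. A natural question is
whether the metabolic and relaxometric hotspots occupy the *same* tissue.

`mrhotspot` implements a subject-by-subject, cohort-aggregated analysis of
that question:

1. **Regions of interest.** From a tumor segmentation TU and a white-matter
   mask, build TU+PT (TU dilated by 6 face-connected voxel iterations;
   6 × 3.4 mm ≈ 2 cm, a peritumoral layer), PT = TU+PT \ TU, and the
   normal-appearing white matter reference NAWM = (WM \ TU+PT) eroded once.
2. **MRSI quality control.** Discard voxels with linewidth
   FWHM > 0.15 ppm, SNR < 5, metabolite CRLB > 80 %, or a spectral-fit
   coefficient more than 13 median-absolute-deviations from the median; a
   ratio voxel is kept only if both metabolites pass.
3. **Hotspot definition.** For each quantitative map *m* and region *R*,
   the hotspot is the set of voxels in *R* with value strictly greater than
   1.5 × median(*m* over NAWM).
4. **Spatial similarity.** Between hotspots A and B: the Sørensen–Dice
   coefficient DSC = 2|A∩B| / (|A|+|B|), and the distance between
   intensity-weighted centers of intensity (COID), in cm.
5. **Cohort statistics.** Subject-level hotspot medians are aggregated as
   cohort median (interquartile range); TU vs. PT contrasts use a two-sided
   paired t-test.

Because patient data cannot ship with the package, a **synthetic phantom
generator** produces cohorts with known planted region levels, multiplicative
Gaussian noise, between-subject level jitter, and planted quality defects, so
that every stage of the pipeline can be validated against ground truth.

## Worked example

Simulate a 4-subject phantom cohort on a 32 × 32 × 24 grid (3.4 mm voxels)
and run the full analysis:

```sh
mrhotspot simulate --out demo/cohort --subjects 4 --seed 11 --shape 32 32 24
mrhotspot run --input demo/cohort --out demo/run --seed 11
cat demo/run/tables.txt
```

Actual output (excerpt of `tables.txt`; values are cohort medians with
quartiles in parentheses):

```
Median values in regions of interest
 Quantity                            TU                            PT TU vs. PT p                         TU+PT                  NAWM
  gln_tcr          0.902 (0.894, 0.911)           0.671 (0.67, 0.672)    6.28e-05          0.676 (0.675, 0.677)     0.32 (0.32, 0.32)
 gln_tnaa          0.609 (0.604, 0.615)           0.381 (0.38, 0.381)    1.15e-05          0.383 (0.383, 0.384)     0.16 (0.16, 0.16)
  ...
       t1 1.75e+03 (1.74e+03, 1.75e+03) 1.76e+03 (1.76e+03, 1.76e+03)      0.0932 1.76e+03 (1.76e+03, 1.76e+03)        949 (948, 950)
       t2             84.6 (84.3, 85.3)                102 (102, 102)    1.81e-05                101 (101, 102)     42.7 (42.7, 42.8)

DSCs between hotspots
      DSC between                TU             TU+PT                PT
       t1 and ROI 0.98 (0.98, 0.98) 0.99 (0.98, 0.99) 0.99 (0.99, 0.99)
 gln_tnaa and ROI 0.95 (0.93, 0.96) 0.95 (0.95, 0.95) 0.95 (0.95, 0.95)
  gln_tnaa and T1 0.92 (0.91, 0.93) 0.94 (0.93, 0.94) 0.94 (0.93, 0.94)
  gln_tnaa and T2 0.95 (0.93, 0.96) 0.95 (0.95, 0.95) 0.95 (0.95, 0.95)
  ...
```

The generator planted Gln/tNAA levels of 0.61 (tumor), 0.38 (peritumoral)
and 0.16 (NAWM); the pipeline recovers 0.609, 0.381 and 0.16 from the noisy
volumes, the TU-vs-PT paired t-test detects the planted contrast
(p ≈ 1e-05), and the T1 map (planted with nearly no TU-vs-PT contrast,
1724 vs 1756 ms) correctly shows no significant difference (p = 0.09).
Machine-readable TSVs (`subject_medians.tsv`, `similarity.tsv`,
`cohort_*.tsv`) and a `run_log.json` with the exact configuration are written
alongside.

The same analysis is available from Python:

```python
from mrhotspot import (PhantomSpec, generate_subject, build_roi_set,
                       nawm_reference_median, define_hotspot, dice)

ds, truth = generate_subject(PhantomSpec(shape=(32, 32, 24)), seed=11)
roi = build_roi_set(ds.tu, ds.wm)                 # TU / TU+PT / PT / NAWM
m = ds.maps["gln_tnaa"]
ref = nawm_reference_median(m, roi.nawm)
hs = define_hotspot(m, roi.tu, ref, threshold_factor=1.5)
print(dice(hs.mask, roi.tu))
```

## Running the tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end validation suite; the other
modules test each stage against independent brute-force oracles (set-algebra
enumeration for Dice, weighted-sum centroids, the textbook paired-t formula,
L1-ball dilation).

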