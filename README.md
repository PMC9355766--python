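# dentinemp

Quantitative aging analysis of multiphoton microscopy images of human
dentine, aimed at forensic age estimation. Dentine — the collagen-rich
mineralized tissue forming the bulk of a tooth — changes measurably with
age: the hypermineralized peritubular sheaths thicken, and the SHG-active
collagen signal declines relative to autofluorescence. `dentinemp`
implements the image-analysis chain that turns paired two-photon excited
fluorescence (TPEF) and second-harmonic generation (SHG) acquisitions into
age-sensitive metrics, and a synthetic-image generator that makes every
stage verifiable by parameter recovery.

## What is measured

For each imaged dentinal region (a 180 × 180 µm² field):

- **INAG** (index of aging), the normalized TPEF/SHG contrast

  INAG = (Ĩ_SHG − Ĩ_TPEF) / (Ĩ_SHG + Ĩ_TPEF) ∈ [−1, 1],

  with Ĩ the spatial mean intensity. Dentine emits less SHG than TPEF, so
  INAG is negative and becomes more negative with age.
- **Peritubule size**: the dominant orientation of the elongated tubules is
  found by Otsu thresholding + Hough voting; intensity cross-sections
  perpendicular to it show tops and valleys, and the size is the distance
  between consecutive valleys (µm).
- **Structural dispersion (SD)**: the spread (degrees) of local fiber
  orientations from the gradient structure tensor; SD ≤ 20° marks a
  quasi-aligned (organized) arrangement, SD > 40° a disorganized one.
- **ρ, the hyperpolarizability ratio** of collagen under cylindrical
  symmetry, from three SHG images at linear polarizations 0°/90°/60°:
  the response I(Δ) ∝ sin²(2Δ) + [sin²Δ + ρ·cos²Δ]² (Δ = angle between
  polarization and fiber axis) gives |ρ| from the parallel/perpendicular
  intensity ratio and the sign from the oblique state. ρ is negative in
  dentinal collagen; its magnitude grows with internal nanoscale order.

Specimen-mean metrics are regressed on age by ordinary least squares
(slope, intercept, Pearson R, two-sided p), with Mann–Whitney U for sex
comparisons and relative-change statements evaluated on the fitted lines.

## Worked example

`examples/05_full_pipeline.py` simulates a small noiseless cohort whose
ground truth lies exactly on the regression lines reported for real teeth
(width 0.03·age + 3.47 µm, INAG −0.003·age − 0.25, ρ −0.02·age − 1.03),
then measures the rendered images and refits:

```
metric        slope      intercept   R        p
width_um      +0.03135    +3.4248  +0.9981  9.72e-05
inag          -0.00300    -0.2500  -1.0000  1.20e-30
rho_mean      -0.02001    -1.0293  -1.0000  3.15e-10

INAG magnitude change, age 20 -> 80: 58.1%
```

The fitted slopes recover the configured lines: the width estimate is
pixel-limited (hence the small wobble), while INAG and ρ invert exactly on
noiseless renders. The last line evaluates the INAG line at ages 20 and
80: the index magnitude is ~58% larger at 80.

The other examples demonstrate one capability each (simulation, INAG,
morphometry, polarimetry); all write any file output under the current
directory.

## Command line

A thin CLI wraps the same pipeline:

```bash
dentinemp simulate --config cohort.json --out data/ --seed 1
dentinemp validate data/
dentinemp analyze --input-dir data/ --out results/
dentinemp report results/regions.csv
```

`analyze` writes `regions.csv`, `specimens.csv`, `report.json` (with the
resolved configuration for provenance) and a log; reruns with the same
config and seed are byte-identical.

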