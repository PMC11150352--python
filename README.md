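# cartimetrics

Quantitative analysis of combined morphologic/quantitative knee MRI,
exercised end to end on a synthetic digital knee phantom.

Prep-interleaved turbo-spin-echo acquisitions deliver two or three
morphologic images whose magnetization-preparation durations (a T2
preparation of 0/50 ms, or spin-lock preparations of 0/25/50 ms at 500 Hz)
impose a known exponential weighting, so that voxel-wise T2 or T1ρ maps come
"for free" with the clinical images.  Evaluating such a sequence against 2D
and 3D TSE references raises three quantitative questions that this package
implements as reusable, tested building blocks:

1. **Defect delineability** — how sharply does each sequence depict a
   standardized full-thickness cartilage defect?  Signal-intensity line
   profiles through the defect are normalized to a maximum of 1 and
   summarized by the full width at half maximum (FWHM, measured between the
   half level of the cartilage-background-to-maximum range) and the edge
   width (EW, the mean 10–90% transition width of the two defect shoulders).
2. **Bone texture** — does the acquisition alter the apparent subchondral
   trabecular texture?  Inside a circular ROI (40 px diameter) the images,
   min–max normalized to [0, 1] and quantized into 200 equal bins, yield a
   gray-level co-occurrence matrix (distance 1, four in-plane directions,
   symmetric); first-order variance, joint energy `Σ p²`, joint entropy
   `−Σ p log₂ p` and inverse difference `Σ p/(1+|i−j|)` are averaged over
   the directions.
3. **Regional relaxometry** — do cartilage T2 and T1ρ change after defect
   creation?  Maps are fitted voxel-wise by log-linear least squares on
   `ln S(τ) = ln S₀ − τ/T` and summarized as mean ± SD per cartilage region
   (anterior/central/posterior femur, tibia, and the voxel-weighted pool),
   alongside a caliper-style thickness measurement quantized to one voxel.

Because the cadaveric source images of the motivating experiment are not
publicly deposited, the package ships a first-class digital phantom: a
sagittal knee-like geometry (condyle, cartilage band, fluid, tibial plateau,
textured fatty marrow) with fluid-filled defects of 3/5/8 mm diameter,
imaged through the ideal prep-weighted signal equation
`S(x, τ) = PD(x)·exp(−τ/T_c(x))·f(x)` with per-sequence Gaussian PSF blur
and Rician noise.  The statistics module implements the study design's
battery: repeated-measures ANOVA with Tukey–Kramer post hoc comparisons,
exact Wilcoxon matched-pairs signed-rank tests, the two-tailed paired
t-test, Cohen's *d*, and the z-approximation minimum sample size — all with
a family-wise significance level of α = 0.01.

## Worked example

```python
from cartimetrics import (PhantomSpec, build_phantom, simulate_stack,
                          t2prep_params, map_relaxation, regional_stats,
                          min_sample_size)
from cartimetrics.regional import erode_regions

spec = PhantomSpec(seed=1)            # defects 3/5/8 mm, 0.27 mm voxels
model = build_phantom(spec)
stack = simulate_stack(model, t2prep_params(blur_sigma_mm=0.3),
                       noise_sigma=20.0, seed=1)
t2_map = map_relaxation(stack, floor=60.0, cap=500.0)
labels = erode_regions(model.region_labels, 2)   # partial-volume guard
print(regional_stats(t2_map, labels).round(1))
print("minimum sample size:", min_sample_size(power=0.80, alpha=0.01, d=1.24))
```

prints

```
  region  mean_ms  sd_ms  n_voxels  valid
0     aF     49.6    7.3       295   True
1     cF     53.2    7.8       217   True
2     pF     65.0   11.2       177   True
3      T     42.0    5.9       533   True
4    all     49.2   10.9      1222   True
minimum sample size: 8
```

The regional means recover the phantom's ground-truth T2 of 48/51/64/41 ms
(anterior/central/posterior femur, tibia) to within ~2 ms under SNR-50
Rician noise; the residual upward offset is the expected noise-floor bias of
magnitude data.  The `all` row pools the four regions voxel-wise.  The
sample-size line reproduces the paired-design z-formula
`n = ⌈((z_{1−α/2} + z_{power})/d)²⌉` at power 80%, α = 0.01 and d = 1.24.

A full cohort emulation — ten specimens imaged pre and post defect creation,
all three analysis arms, statistics included — runs in a few seconds:

```sh
cartimetrics run --out results/ --n-specimens 10 --seed 7
```

which writes `study_table.csv` (long-format specimen × sequence × metric
records) and `report.json` (test statistics and multiplicity-adjusted
p-values per arm).  `cartimetrics simulate`, `fit`, `delineate` and
`texture` expose the individual stages on NIfTI inputs and outputs.

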