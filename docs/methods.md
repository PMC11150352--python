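# Methods

## Signal model and phantom

The phantom emulates a sagittal slice through the lateral femorotibial
compartment on a regular voxel grid (default 192 × 192 at 0.27 mm in-plane,
one or more identical-geometry slices).  Geometry is analytic: a circular
femoral condyle (bone radius 16 mm, 1 mm cortical shell, trabecular marrow
inside) carries a cartilage band of default thickness 3.0 mm over the
inferior 150° arc; a flat tibial plateau with a 2.5 mm cartilage layer sits
below; synovial fluid fills the joint space.  World coordinates are
`index × spacing` in mm, 0-based, with no rotation.

Defects are slots of the nominal width (3, 5, 8 mm by default) cut through
the full thickness of the band perpendicular to the bone contour — the
digital analogue of a biopsy punch — placed anterior → posterior at
−38°/0°/+38° from the inferior apex and filled with fluid.  Placement
raises an error naming the offending diameter whenever two defects would
come within 0.5 mm of each other or of the band edge.  Disabling defects
with the same seed yields the voxel-identical pre-defect twin.

Image formation models only the preparation dimension:

    S(x, τ) = PD(x) · exp(−τ / T_c(x)) · f(x)

with `T_c` = T2 for the T2-preparation family (τ = 0, 50 ms) and T1ρ for the
spin-lock family (τ = 0, 25, 50 ms; the 500 Hz spin-lock frequency is
metadata only).  Echo-train contrast, TR/T1 saturation and receive profiles
are deliberately absorbed into the proton-density map: the mapping analysis
only ever uses ratios across τ.  `f` is a scalar fat-suppression factor
(default 0.05) applied to fat-flagged voxels on fat-suppressed echoes — a
spectral model is out of scope.  Sequence sharpness is a Gaussian PSF
(reflective boundary, kernel truncated at 4σ; blur conserves total
intensity to < 0.1%), and noise follows the magnitude-MRI Rician law
`sqrt((S+n₁)² + n₂²)`, `n₁,n₂ ~ N(0, σ²)`.  Zero blur and zero noise
reproduce the ideal signal exactly, which is what makes the relaxometry
round-trip test exact.

### Tissue parameters

Per-tissue defaults (PD arbitrary units; T2/T1ρ ms): cartilage 400/50/40,
fluid 1000/200/150, marrow 900/60/65 (fat-flagged), muscle 350/30/35,
cortical bone 120/5/6.  Cartilage relaxation times are overridden
region-wise; the defaults (T2 48/51/64/41 ms and T1ρ 43/41/34/36 ms for
anterior/central/posterior femur and tibia) reproduce the pre-defect means
reported for cadaveric knees, so that the emulated cohort's Table-shaped
outputs land on the reported scale.  Cartilage PD is set well below fluid
because on PD-weighted fat-saturated images fluid is the brightest tissue
and cartilage intermediate; this contrast is also what makes the 10–90%
edge crossings resolvable above noise.

Trabecular texture is a seeded multiplicative field on marrow PD: Gaussian
white noise smoothed at 0.5 mm, unit-normalized, amplitude 0.05.  The
amplitude was chosen so that the texture ROI's normalized intensities
occupy roughly 40–50 of the 200 quantization bins under the study's blur
and noise, the occupancy range reported for the real acquisitions.  The
field has no anisotropy and no plate/rod architecture, so texture features
are meaningful only in relative (between-sequence) comparisons.

## Relaxometry

Voxel-wise mono-exponential fitting is log-linear least squares on
`ln S = ln S₀ − τ/T`, unweighted.  With two echoes this is algebraically the
closed form `T = Δτ / ln(S₁/S₂)`; with three it remains exact on exact data
and deterministic — a nonlinear fit would add iteration-dependence without
benefit at 2–3 points.  A voxel is invalid (mask false, value NaN) when any
signal is at or below the validity floor, when the signal fails to decay
(`S_last ≥ S_first`), or when the fitted T is non-positive or exceeds the
cap (default 500 ms — loose relative to the 0–100 ms display scale of
cartilage maps, to avoid clipping fluid or pathology).  The floor default in
the pipeline is 3× the Rician noise level.  Rician noise biases log-linear
estimates upward at low SNR; the tests assert that the cartilage-mean bias
is ≤ 2% at SNR 50 and decreases monotonically as σ → 0.

## Delineability

Profiles are sampled by bilinear interpolation at uniform arc-length steps
(default ¼ of the in-plane spacing) between world-space endpoints; the
phantom provides the endpoints analytically (tangent to the band through
each defect center, 3 mm of cartilage flank per side), standing in for the
manual annotation used on real images.  After normalization to max 1 the
cartilage background is the mean of the two 20%-flank means (the original
procedure does not define it; flank averaging is symmetric and robust).

* FWHM: half level `h = bg + 0.5(1 − bg)`; crossings are linearly
  interpolated, taking the crossing nearest the global maximum on each
  side (the defect is the bright fluid-filled peak).  A profile that never
  crosses `h` on both sides raises a no-defect error.
* Edge width: per shoulder, the distance between the 10% and 90% crossings
  nearest the maximum; EW is the mean of the two shoulders.  Two threshold
  conventions are implemented because the source text ("10% and 90%
  maximum SI") is ambiguous: `absolute` (fractions of the normalized
  maximum — the literal reading, and the function default) and `relative`
  (fractions of the background-to-maximum range).  With cartilage flanks at
  ~0.6 of the maximum the absolute 10% level is unreachable and raises an
  explicit error; the study pipeline therefore uses the relative mode.

On the phantom, FWHM recovers the nominal diameters within ±0.5 mm for PSF
σ ≤ 0.5 mm, and EW grows strictly with blur (≈ 2.563 σ_total per erf edge),
which is the directional fingerprint of a sharper versus blurrier sequence.

## Texture

Feature mathematics are implemented directly rather than delegated to a
radiomics package, and are verified against brute-force pair enumeration.
Normalization is min–max over the whole stack; quantization uses a fixed
bin count (200) over [0, 1] with upper-edge clamping.  The GLCM uses
distance-1 offsets {(0,1),(1,1),(1,0),(1,−1)}, symmetric accumulation, one
matrix per offset normalized to sum 1, features averaged over offsets —
the documented conventions of the commonly used radiomics implementation,
all configurable.  ROI membership is voxel-center-within-radius.  Entropy
uses a machine-epsilon guard inside the logarithm and is clipped at zero.
First-order variance is the population variance of the normalized (not
quantized) ROI values by default.  Under increasing PSF blur, energy and
inverse difference rise strictly and entropy falls — the direction of the
reported difference between the blurrier prep-interleaved acquisition and
the 3D reference.

## Regional statistics and thickness

Regional means/SDs are computed over voxels that are in the region label
*and* in the map validity mask; regions with no valid voxels are flagged,
never dropped.  The "all regions" row pools voxel-wise
(`Σ nᵢmᵢ / Σ nᵢ`) rather than averaging region means; the voxel counts are
reported so either convention can be recomputed.  In the study pipeline the
region masks are first eroded by 2 voxels in-plane: without this guard,
partial-volume mixing with adjacent fluid (T2 200 ms) inflates the thin
regions by up to ~6 ms at the pipeline's PSF.  Region boundaries in the
phantom are equal arc-length thirds of the femoral band, since
meniscus-based anatomical landmarks have no synthetic counterpart.

Thickness mimics a digital caliper: starting at the cartilage mid-surface
next to the 8 mm defect, contiguous cartilage voxels are counted along the
surface normal in one-voxel steps, so the result is quantized to the pixel
size — exactly the resolution limit of the manual instrument.  It is
measured on the label mask, not on simulated images, because manual caliper
placement on images is operator-defined.

## Statistics

* RM-ANOVA: one-way within-subject, `F = MS_cond/MS_err` with df
  `(k−1, (k−1)(n−1))`; no sphericity correction (k = 3 with a post hoc test
  covers the intended use).  Perfectly additive data give `MS_err = 0` and
  an infinite F, handled explicitly.
* Tukey–Kramer: all pairwise `q = |mᵢ−mⱼ|/√(MS_err/n)` against the
  studentized-range distribution with the ANOVA error df.  For k = 2 this
  collapses exactly to the paired t-test (`q = t√2`), which the tests
  assert together with `F = t²`.
* Wilcoxon matched-pairs signed-rank: zeros discarded (classical
  convention, also the default of the commercial package used in the
  original analysis), mid-ranks for ties; exact two-sided p from the full
  null distribution of W⁺ (rank-polynomial convolution on doubled ranks,
  n ≤ 25 — the study has n = 10) and a tie-corrected normal approximation
  above.  Exactness is verified against 2ⁿ enumeration for n ≤ 12.
* Paired t and Cohen's d use the paired-differences convention
  `d = mean(Δ)/sd(Δ)`.
* Minimum sample size: the z-approximation
  `n = ⌈((z_{1−α/2} + z_{power})/d)²⌉` is the default — at power 0.80,
  α = 0.01 two-sided and d = 1.24 it yields n = 8, matching the reported
  power analysis, whose exact method was not stated; an explicit
  noncentral-t mode is provided and returns a larger (more conservative) n.

Study-level reports fix the family-wise α at 0.01 and always report
multiplicity-adjusted p-values.

## Study emulation

The pipeline simulates n = 10 specimens (unique seeds spawned from one base
seed).  Inter-specimen variability is lognormal: one multiplier per
specimen on all regional T2 values (σ = 0.08, giving across-specimen SDs of
~3–4 ms as reported), an independent one for T1ρ, and one on cartilage
thickness (σ = 0.15, SD ≈ 0.45 mm).  The post-defect state adds the
configured regional elevations (defaults +1/+5/+5/+4 ms T2 and
+3/+2/+5/+4 ms T1ρ — the reported pre-to-post changes), a per-region
N(0, 1.5 ms) session jitter emulating repositioning and re-segmentation
between the two scans, and 0.2 mm cartilage swelling.  The jitter level
makes the small injected shifts statistically unreliable (as observed for
the anterior femur) while the +5 ms central-femur elevation remains
detectable by the exact Wilcoxon test at α = 0.01.

Acquisition settings: per-sequence PSF σ of 0.30/0.40/0.45 mm for the 2D
reference, 3D reference and prep-interleaved sequence (sharpest-to-
blurriest, mirroring the reported ordering); the map-generating stack uses
σ = 0.30 mm; Rician σ = 20 against a fluid PD of 1000 (SNR 50).  Everything
is deterministic given the seeds, and one full cohort takes a few seconds
on one CPU (192² voxels, single slice) — problem sizes chosen so the whole
suite and the acceptance script run at desk scale.

## Known limitations

* No k-space, coil, B1 or fat-spectral modeling; fat suppression is scalar.
* No TR-dependent T1ρ saturation: the phantom cannot reproduce (and does
  not attempt to reproduce) the anomalous T2 > T1ρ ordering observed in
  vivo with short-TR spin-lock protocols.
* Phantom geometry is a single analytic slice; marrow texture is isotropic
  smoothed noise, not trabecular architecture, so absolute texture-feature
  values carry no biological meaning.
* Absolute signal intensities are arbitrary by construction; only
  τ-ratios, widths and between-condition contrasts are meaningful.
* Passing tests demonstrate correctness of the estimators on data that
  satisfy the generative model; they do not validate the metrics against
  real scanner data.
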