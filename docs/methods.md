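# Methods

## Model

The image-quality statistic is the liver signal-to-noise ratio
SNR = SUVmean/SD measured in a 3-cm spherical VOI placed in homogeneous
liver, at least 1 cm from the organ boundary to avoid partial-volume
contamination. Assuming Poisson counting statistics, noise scales with
the square root of collected counts, so dividing by the square root of
the dose–time product DTP = activity × minutes-per-bed-position yields a
normalized quantity SNRnorm = SNR/√DTP that is, in expectation,
independent of injected activity and scan duration. SNRnorm is then a
property of the patient and scanner only, and its habitus dependence is
modelled as SNRnorm = a·p^(−d) for a patient-dependent parameter p.
Inverting at a target SNR gives the regimen
DTP(m) = (SNR_target/a)²·m^(2d).

Assumptions worth keeping in mind: pure Poisson noise (no reconstruction
correlations), a homogeneous liver over the VOI, and independence of the
calibration (liver SUVmean) from acquisition time.

## Synthetic data

The generator reproduces the study conditions rather than any particular
patient:

- **Cohort**: seven 10-kg body-mass strata from 50–120 kg, three
  subjects each (21 total); masses uniform within strata; lengths
  N(1.74 m, 0.10 m) truncated to (1.5, 2.0) m for both sexes; sex
  Bernoulli with male fraction 12/21. These choices match the published
  aggregate cohort moments; per-subject sex/length pairs are not public,
  so only aggregates are reproducible. Lean body mass uses the
  Janmahasatian fat-free-mass equations (male 9270·W/(6680+216·BMI),
  female 9270·W/(8780+244·BMI)).
- **Dosing**: 1.5 MBq/kg, 6-min parent acquisition
  (DTP = 9·m MBq·min at full time).
- **Phantom**: 100×100×60 voxels of 4.1×4.1×3.0 mm. Only the in-plane
  pixel size is a published reconstruction parameter; the 3-mm slice
  matches the CT slice thickness and is a package choice. The liver is
  an 80×60×50 mm semi-axis ellipsoid offset laterally inside a torso
  ellipsoid; background SUV 1, liver SUV 5.8, optionally one 22-mm
  abdominal lesion at SUV 30 (matching the reported lesion SUVmean
  scale). Liver voxels are independent Poisson with rate
  λ = (a·m^(−d))²·DTP using the generating values a = 19.6, d = 0.95, so
  the expected VOI SNR is exactly a·m^(−d)·√DTP; the count→SUV
  calibration is 5.8/λ. Rates below 1 count/voxel are rejected rather
  than simulated — the normalization argument needs meaningful count
  statistics.
- **Thinning**: each voxel count is replaced by a Binomial(count, f)
  draw, f = mbp/6. This maps Poisson(λ) marginals to Poisson(fλ) and
  preserves the nested-subset correlation structure of retrospective
  list-mode subsampling, unlike regenerating independent volumes. The
  calibration is rescaled by 1/f so the expected SUV image is unchanged.

What the generator does *not* emulate: attenuation, scatter,
reconstruction point-spread correlations, Gibbs ringing, TOF/PSF
effects, liver inhomogeneity and count-rate (NECR) non-linearity.
Passing tests therefore demonstrate the internal consistency of the
normalization-fit-regimen chain under its own Poisson assumptions, not
the behaviour of a clinical reconstruction. In particular the real-data
scatter that produced R² ≈ 0.6–0.7 and a wide confidence interval for d
is absent here: synthetic fits have R² near 1 and much tighter
intervals.

## Measurements

- VOI rasterization: a voxel belongs to a sphere iff its center
  (world coordinate = index × spacing, 0-based) lies within the radius.
  A sub-voxel sphere keeps the voxel nearest the center.
- SNR uses the unbiased (n−1) SD. A constant region raises rather than
  returning an infinite SNR.
- SUVpeak: mean over a 1-cm³ spherical kernel (radius (3/4π)^(1/3) cm ≈
  6.2 mm, 21 voxels at the default spacing), maximized over kernel
  positions whose center voxel lies in the VOI; kernels are cropped at
  the grid edge and the result flagged when that happens. The kernel may
  extend beyond the VOI — a declared choice where conventions differ.
- 50 %-threshold SUVmean: 26-connected component of
  {SUV ≥ 0.5·SUVmax} ∩ VOI seeded at the SUVmax voxel, inclusive
  threshold. 26-connectivity is the common 3-D choice and is fixed so
  tests can be exact.
- Lesion-count categories: 0, 1, 2, 3–5, 6–10, >10 → ordinal 0–5.

## Fitting and regimen

Per patient, SNRnorm is averaged over all reconstructions (1–6 mbp) and
the power law fitted by unweighted nonlinear least squares on the
natural scale (`scipy.optimize.curve_fit`), initialized from the log–log
ordinary regression. R² is computed on the natural scale as
1 − SSres/SStot. The 95 % interval for d is Wald/t with n−2 degrees of
freedom — the reference analysis does not state its CI construction, so
the simplest defensible default is used. Residuals are reported as
(fit−observed)/fit·100 %, whose SD is the cross-parameter comparison
statistic; the comparison test itself (one-way ANOVA) is standard
machinery left to statistical packages.

The regimen keeps (SNR_target/a)² at full precision: the printed
two-decimal coefficient 0.10 would shift required activities by several
MBq at the extremes (the 55- and 124-kg endpoints round to 68 and
317 MBq only with the exact 0.10006…). Activities round half-up to whole
MBq. Guideline crossover masses are defined operationally as the
smallest integer mass whose unrounded required activity exceeds the
guideline level; the continuous solutions are reported alongside.

## Reader agreement

Median ordinal scores use the lower median for even counts, keeping the
summary an attained category. Fleiss' kappa follows the standard
formulation with the Fleiss–Nee–Landis large-sample SE and a normal 95 %
CI; a table with all mass in one category has chance agreement 1 and
returns a flagged degenerate result. The published kappa values cannot
be recomputed from marginal count tables alone, so the module validates
against hand-computed tables and an independent implementation instead;
a latent-quality reader simulator (true score from SNR thresholds plus
per-reader Gaussian noise) generates realistic rating tables.

## Problem sizes and determinism

The acceptance script evaluates the regimen arithmetic exactly and the
stochastic quantities from nine independent 21-patient replicas at the
full 100×100×60 grid, reporting medians; unit tests use a shrunken
48×48×36 geometry where the grid size is immaterial. All randomness
descends from a single integer seed through `numpy` seed sequences, with
one substream per patient volume; replica outputs are byte-reproducible
per seed.

## Known limitations

- The fitted amplitude a is strongly correlated with d along a ridge
  (â scales like m_geo^(d̂−d)), so single-replica estimates of a scatter
  by ~10 %; medians over seeds are reported for that reason.
- Independent-voxel noise makes the VOI SD estimator slightly optimistic
  relative to reconstructed PET, where voxel correlations reduce the
  effective sample size.
- No NECR modelling: the regimen extrapolates linearly in DTP even at
  activities where real scanners saturate.
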