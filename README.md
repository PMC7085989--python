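# petdose

Body-mass-based dosing for ⁶⁸Ga-DOTA-TATE PET image quality.

PET image quality degrades with patient size: a fixed injected activity
and scan time give heavier patients visibly noisier images. `petdose`
implements, as a fully tested simulation pipeline, the analysis that
turns this observation into a weight-based dose regimen for
somatostatin-receptor PET in neuroendocrine-tumor imaging:

1. **Image quality** is measured as the liver signal-to-noise ratio —
   the SUVmean of a 3-cm spherical VOI in homogeneous right liver
   divided by its SD — and normalized by the dose–time product
   DTP = activity (MBq) × minutes per bed position (min):

   SNRnorm = SNR / √DTP    [(MBq·min)^(−1/2)]

   Under Poisson counting statistics SNRnorm is independent of how much
   activity was injected and how long the scan took.
2. **Habitus dependence** is modelled with a power law in a
   patient-dependent parameter p (body mass m, length, BMI, mass/length
   or lean body mass): SNRnorm = a·p^(−d), fitted by nonlinear least
   squares. For body mass the reference values are a = 19.6, d = 0.95.
3. **The regimen** inverts the fit at a target SNR: the dose–time
   product needed to give every patient the same image quality is

   DTP(m) = (SNR_target / a)² · m^(2d)

   which at SNR_target = 6.2 becomes DTP ≈ 0.10 · m^1.9 MBq·min.

Because no public PET data accompany the analysis, the package ships a
first-class synthetic-data layer: stratified cohorts (seven 10-kg strata
from 50–120 kg, three subjects each, 1.5 MBq/kg dosing) and count-domain
phantoms whose liver voxels are Poisson with rate (a·m^(−d))²·DTP, so the
expected liver SNR follows the model by construction. Shorter
acquisitions are emulated by binomial count thinning, the in-silico
equivalent of retrospectively subsampling list-mode data into 1–6-min
reconstructions. Reader-study arithmetic (ordinal median scores, Fleiss'
kappa for multiple raters) is included for agreement analyses.

Intended users: medical physicists and nuclear-medicine researchers who
want to reproduce, stress-test or re-parameterize weight-based dose
regimens for quantitative PET.

## Worked example

```python
import numpy as np
from petdose import (
    StudyConfig, run_replica, reference_regimen,
    activity_for_mass, crossover_mass,
)

# exact regimen arithmetic at the reference fit (a=19.6, d=0.95, SNR 6.2)
reg = reference_regimen()
print(round(reg.coefficient, 4), reg.exponent2d)
# 0.1001 1.9                       → DTP ≈ 0.10 · m^1.9
print(activity_for_mass(reg, 55, 3), activity_for_mass(reg, 124, 3))
# 68.0 317.0                       → MBq needed at 3 min/bed, 55 vs 124 kg
print(crossover_mass(reg, 100, 3).mass, crossover_mass(reg, 200, 3).mass)
# 68 98                            → kg where a 100–200 MBq guideline is crossed

# full stochastic replica: 21 simulated patients, thinned to 1–6 min/bed
res = run_replica(StudyConfig(seed=1))
print(round(res.fit.a, 2), round(res.fit.d, 3), round(res.fit.r2, 3))
# 23.17 0.985 0.985                → fitted a, d, R² for this seed
print(round(res.metrics.query("mbp_min == 6").liver_suv_mean.mean(), 2))
# 5.79                             → cohort-mean liver SUVmean at 6 min/bed
```

The fitted (a, d) pair is strongly correlated along a ridge, so a single
replica scatters noticeably around (19.6, 0.95); medians over several
seeds concentrate tightly (see below).

A command-line interface mirrors the pipeline:

```sh
petdose run-study --out out/ --seed 1     # full replica + report bundle
petdose regimen --a 19.6 --d 0.95 --target-snr 6.2 --mbp 3
petdose simulate-cohort --seed 1 --out cohort.csv
```

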