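# dcekin

Quantitative dynamic contrast-enhanced MRI (DCE-MRI) analysis for tracking
anti-angiogenic treatment response, built around the setting of metastatic
renal cell cancer under tyrosine kinase inhibitor (TKI) therapy: patients
are scanned at baseline and at weeks 4 and 10 after starting treatment, and
perfusion biomarkers derived from each scan are tested for association with
progressive disease at 6 months.

The package takes a 4D dynamic series and coarse operator ROIs through the
whole chain:

1. **relative enhancement** — per voxel, `E(t) = (S(t) − S₀)/S₀` with `S₀`
   the mean of the pre-contrast frames; `E` is the concentration surrogate;
2. **arterial input function** — the operator's aorta ROI is refined to the
   voxels whose peak enhancement lies in the 95th–100th percentile band,
   and the AIF is their frame-wise mean;
3. **perfused-tumour segmentation** — a maximum-enhancement map is
   thresholded at a fraction of the within-lesion peak, excluding
   partial-volume periphery and necrosis; the perfused volume (cm³) is the
   retained voxel count × voxel volume;
4. **kinetic modelling** — a single-compartment (Kety/Tofts-type) model

   `Ct(t) = Kᵗʳᵃⁿˢ ∫₀ᵗ Ca(τ) e^(−kₑₚ(t−τ)) dτ`, `kₑₚ = Kᵗʳᵃⁿˢ/(ECV/100)`

   is fitted per lesion by bounded nonlinear least squares, giving
   `Kᵗʳᵃⁿˢ` (min⁻¹), `ECV` (mL/100 mL) and their ratio, the extracellular
   mean transit time `MTT = (ECV/100)/Kᵗʳᵃⁿˢ` (s);
5. **response analysis** — per-patient change tables (largest lesion only,
   absolute and %), paired t-tests across visits, normality-routed
   (Welch t vs Mann–Whitney) progression-group comparisons, ROC/AUC for
   discriminating parameters, and two-reader ICC(2,1) agreement.

A synthetic-phantom module generates 4D scenes (aorta + spherical lesions
with known `Kᵗʳᵃⁿˢ`/`ECV`) and longitudinal cohorts with known progression
structure, so every stage is testable end to end without patient data.

## Worked example

```python
import numpy as np
from dcekin import AcquisitionSpec, AifCurve, TissueCurve, fit_one_compartment
from dcekin.kinetics import one_compartment_curve
from dcekin.phantom import AifModelParams, population_aif

acq = AcquisitionSpec()            # 6 pre-contrast @ 2 s, 120 dynamic @ 2.4 s
t = acq.dynamic_times()
ca = population_aif(t, AifModelParams())
aif = AifCurve(values=ca, frame_times=t, n_voxels=50)

ct = one_compartment_curve(ca, t, 0.96, 40.0)       # truth: 0.96 /min, 40 mL/100mL
obs = ct + np.random.default_rng(0).normal(0, 0.02, size=(25, len(ct))).mean(axis=0)
fit = fit_one_compartment(TissueCurve(values=obs, frame_times=t), aif)
print(fit.ktrans, fit.ecv, fit.mtt)
```

prints

```
0.9590197425348643 39.909158736289335 24.968719808083705
```

i.e. the transfer constant and extracellular volume are recovered to well
under 1% from a noisy 25-voxel ROI mean, and the derived mean transit time
is `(39.9/100)/0.959 × 60 ≈ 25 s`. The scripts in `examples/` walk through
each capability (phantom + fit, AIF + segmentation, cohort statistics, the
full pipeline); `examples/04_full_pipeline.py` prints a complete
treatment-response report.

## Command line

```bash
dcekin simulate --seed 7 --out run/data
dcekin quantify --data run/data --out run/results.csv
dcekin respond  --results run/results.csv --cohort run/data/cohort.csv --out run/report
```

Each command accepts `--config config.yaml` (see `RunConfig`); identical
config + seed gives byte-identical output CSVs.

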