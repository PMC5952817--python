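# cmrperf

Quantitative analysis of adenosine stress-perfusion cardiac magnetic
resonance (CMR) for prognostic evaluation of suspected coronary artery
disease: from dual-bolus time–signal-intensity curves to myocardial blood
flow (MBF) and perfusion reserve (MPR), from per-segment MPR to patient-level
ischemic burden under consensus thresholds, and from adjudicated composite
outcomes to cross-validated penalized-Cox risk models compared by
time-dependent AUC and reclassification metrics. A synthetic-data module
generates perfusion curves, segment maps and survival cohorts with the
statistical structure the analysis assumes, so the entire pipeline runs and
is tested without patient data.

Intended users are imaging scientists and biostatisticians working on
perfusion quantification and risk-model evaluation.

## The model

**Perfusion quantification.** The tissue curve is the convolution of the
arterial input function (AIF) with a tissue impulse response constrained to a
Fermi function

```
h(t) = R · [1 / (exp((t − τ₀ − τd)·k) + 1)] · u(t − τd)
```

where `R` indexes contrast influx, `k` the washout decay rate, `τ₀` the
width of the shoulder, `τd` the blood-pool→myocardium delay (fixed during the
fit) and `u` the unit step. `R`, `k`, `τ₀` are fitted by bounded multi-start
nonlinear least squares; MBF is the impulse-response amplitude at the
delay-aligned origin, `MBF = R/(exp(−τ₀k)+1)`, and `MPR = MBF_stress /
MBF_rest`. The AIF comes from a 1:10 diluted pre-bolus (0.0075 vs
0.075 mmol/kg) scaled by the dose ratio, which avoids the signal saturation
a full-dose blood-pool measurement would suffer.

**Ischemic burden.** Each of 16 AHA segments is split into endocardial and
epicardial halves (32 sub-segments). A sub-segment with `MPR < 1.5` is
ischemic; scarred (LGE) sub-segments are excluded from ischemia assessment.
Burden is the ischemic fraction of left-ventricular mass; the dichotomized
tests use ≥2 visually ischemic AHA segments and ≥10% ischemic myocardium.

**Outcomes.** The composite endpoint is cardiovascular death, nonfatal MI,
aborted sudden cardiac death, or revascularization more than 90 days after
the scan (earlier procedures are blanked, the patients kept); only the first
qualifying event counts.

**Prognosis.** Risk classifiers are Cox proportional-hazards models with an
L1 (lasso) penalty on candidate covariates and age, sex and LGE unpenalized.
Double-loop cross-validation (inner folds select the penalty by
partial-likelihood deviance with the one-standard-error rule; outer folds
with repeated restarts yield out-of-fold 2-year event probabilities
`1 − S₀(730 d)^exp(lp)`) feeds the IPCW cumulative/dynamic AUC, the
categorical net reclassification improvement over the <1% / 1–3% / >3% risk
bands, and the integrated discrimination improvement.

## Worked example

```python
import pandas as pd
from cmrperf import synthetic, perfusion

spec = synthetic.AcquisitionSpec(noise_sd=0.0)
stress = [synthetic.TissueGroundTruth.from_mbf(m) for m in (2.4, 1.1, 2.6, 1.0)]
rest = [synthetic.TissueGroundTruth.from_mbf(m) for m in (1.2, 1.0, 1.1, 0.9)]
study = pd.concat(
    [
        synthetic.generate_dual_bolus_study(spec, stress, phase="stress"),
        synthetic.generate_dual_bolus_study(spec, rest, phase="rest"),
    ],
    ignore_index=True,
)
estimates, mpr = perfusion.quantify_study(study, taud=0.0)
print(mpr.round(2).to_string(index=False))
```

prints

```
patient_id  aha_segment half  mbf_stress  mbf_rest  mpr
      P001            1 endo         2.4       1.2 2.00
      P001            1  epi         1.1       1.0 1.10
      P001            2 endo         2.6       1.1 2.36
      P001            2  epi         1.0       0.9 1.11
```

The simulated study contains the diluted pre-bolus AIF, the saturated
main-bolus AIF and four tissue curves; quantification rebuilds the reference
AIF from the pre-bolus, deconvolves each tissue curve, and recovers the
generating MBF values exactly on noiseless data. Sub-segments 1-epi and
2-epi (MPR 1.10, 1.11 < 1.5) would be scored ischemic; with equal masses the
MPR ischemic burden would be 2/4 of the simulated myocardium.

A command-line interface wraps the same stages:

```
cmrperf simulate cohort --seed 1 --out data/
cmrperf adjudicate --cohort data/cohort.csv --out data/survival.csv
cmrperf prognosis --data analysis.csv --model baseline --model mpr --out results/
```

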