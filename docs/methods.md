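# Methods

This note records the models implemented in `cmrperf`, the assumptions they
make, the defaults and why, and the design choices taken where more than one
reasonable convention exists.

## Perfusion quantification

### Forward model

A tissue time–signal-intensity curve is modelled as the rectangle-rule
discrete convolution of the arterial input function (AIF) with a tissue
impulse response on a shared uniform grid of spacing Δt:

    tissue(tᵢ) = Δt · Σ_{j≤i} aif(tⱼ) · h(tᵢ − tⱼ)

with the impulse response constrained to a Fermi function

    h(t) = R · [1/(exp((t − τ₀ − τd)·k) + 1)] · u(t − τd),   u(0) = 1.

`R` (dimensionless) indexes contrast influx, `k` (s⁻¹) the washout decay
rate, `τ₀` (s) the shoulder width during which little contrast has left the
region, `τd` (s) the bolus-arrival delay between the left-ventricular blood
pool and the myocardium. The same discretization is used by the simulator
and the fitter, so noiseless round trips are limited only by optimizer
tolerance, not discretization bias.

### MBF evaluation convention

MBF is the impulse-response amplitude at the time origin. A literal h(0)
with τd > 0 would be zero because of the step factor; time is therefore
aligned by the delay, and

    MBF = R / (exp(−τ₀·k) + 1),

which is continuous in τd and matches established Fermi-deconvolution
practice. Without proton-density normalization and tissue-density constants,
MBF is reported in relative units; MPR = MBF_stress/MBF_rest is unit-free
and is the only quantity consumed downstream.

### Fitting

`R`, `k`, `τ₀` are fitted by bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`); `τd` stays fixed. Bounds are
R ∈ (0, 50], k ∈ (0, 5] s⁻¹, τ₀ ∈ [0, 30] s, covering physiological flows
with generous margin. A 3×3×3 start grid (R ∈ {0.5, 2, 10},
k ∈ {0.05, 0.3, 1.0} s⁻¹, τ₀ ∈ {1, 5, 15} s) guards against local minima;
the lowest-RSS solution is kept, ties broken toward smaller `k`. Convergence
uses a relative RSS tolerance of 1e-8 with at most 500 function evaluations
per start. A fit must explain at least half of the tissue-curve variance
(R² ≥ 0.5) to count as analyzable; contrast-free (noise-only) curves fail
this gate rather than returning spurious flow, mirroring the exclusion of
poor-quality acquisitions from analysis. An identically zero tissue curve
returns R = 0 (zero flow) directly.

### Delay estimation

The delay is estimated from curve onsets: onset = first frame exceeding 10%
of the curve's peak (configurable), delay = tissue onset − AIF onset,
floored at zero. On convolved tissue curves this onset is systematically
late — the convolution rises slowly — so the estimated delay overshoots the
true τd and the fit compensates with a larger amplitude, inflating absolute
MBF. The bias is common to stress and rest and cancels in MPR, which is why
the downstream analysis is unaffected; when absolute MBF matters (as in the
recovery experiments) the true delay should be passed explicitly.

### Dual-bolus AIF correction

The diluted pre-bolus (0.0075 mmol/kg, 1/10 of the main 0.075 mmol/kg dose)
stays within the linear signal range; after baseline correction it is scaled
by the dose ratio (default 10) to reconstruct the unsaturated full-dose AIF.
Baseline correction subtracts the mean of the first n pre-contrast frames
(default 5, minimum 3) and stands in for image-level surface-coil intensity
correction at the curve level.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes, not
the imaging physics:

* **AIF**: gamma-variate bolus
  `dose · gain · ((t−onset)/tp)^α · exp(α(1 − (t−onset)/tp))`, α = 3,
  β = 4 s (peak at tp = αβ = 12 s past onset), gain 2000 signal-units per
  mmol/kg — a standard first-pass bolus shape, single-peaked, zero before
  onset and linear in dose. Default grid: 60 frames at 1 s.
* **Saturation**: the main bolus is compressed through
  `s → c·(1 − exp(−s/c))` with ceiling c = 80 signal-units — smooth,
  monotone, bounded and linear at low signal. Any compressive map with these
  properties would serve; the pre-bolus is emitted unsaturated.
* **Tissue curves**: convolution of the true (unsaturated, full-dose) AIF
  with a Fermi impulse response at known MBF, plus additive Gaussian noise.
* **Noise model**: within a simulated study, noise is applied at uniform
  signal-to-noise ratio across curves: `noise_sd` is the sd on the strongest
  tissue curve (so tissue SNR = peak/noise_sd), and each other curve
  receives noise scaled to its own peak. Equal absolute noise would render
  the diluted pre-bolus (two orders of magnitude below tissue amplitude in
  these relative units) uninformative at any tissue SNR; the uniform-SNR
  choice represents the signal-adaptive gain and blood-pool ROI averaging
  that make the pre-bolus measurement usable in practice.
* **Segment maps**: 16 AHA segments × endo/epi halves with ground-truth MPR
  drawn from Uniform(0.5, 1.4) for ischemic and Uniform(1.8, 4.0) for normal
  sub-segments — a clear margin on both sides of the 1.5 threshold so burden
  arithmetic, not borderline classification, is exercised.
* **Cohorts**: age ~ Normal(58, 13) years clipped to [18, 95], 70% male,
  35.4% LGE-positive, zero-inflated-Beta ischemic burden (55% zeros;
  Beta(1.2, 5.3) otherwise, giving a cohort mean near 8%), event times
  exponential with hazard `λ₀·exp(lp)` per person-year and independent
  exponential censoring capped at 6 years. Defaults λ₀ = 0.0015/yr and
  censoring 0.50/yr were calibrated once against the emulation targets
  (~13% cumulative events, median follow-up ~460 days) under the default
  quantitative-burden coefficients (0.02·age + 2.722·sex + 0.678·LGE +
  2.490·burden). The generator also plants blanked early-revascularization
  procedures in ~10% of patients so adjudication has work to do.

What the generators do **not** emulate: pixel data, motion and k-t
reconstruction artifacts, reader variability in visual scoring (visual flags
mirror ground truth), correlated censoring, competing risks, and calendar
effects. Passing tests therefore demonstrate correctness of the estimators
under the stated statistical model, not robustness to real-data artifacts.

## Ischemic burden

Sub-segment status: LGE excludes a sub-segment from ischemia assessment
regardless of MPR; otherwise MPR < 1.5 (strict) is ischemic and a missing
MPR is non-analyzable. Burden is mass-weighted: the sum of `mass_fraction`
over ischemic sub-segments, with total LV mass (1.0) as denominator — LGE
sub-segments drop out of the numerator only (a renormalized denominator is
available by flag). The ≥2-segment visual rule is applied at the 16-AHA-
segment level (a segment counts once if either half is flagged and it is
scar-free), matching the consensus criterion's definition on AHA segments.
Both dichotomization thresholds are inclusive (≥2 segments, burden ≥ 10%).
Burdens are carried as fractions in [0, 1]; the reported risk-model
coefficient of ~2.5 on quantitative burden is only plausible on that scale.

## Outcomes

Hard events (cardiovascular death, nonfatal MI, aborted sudden cardiac
death) qualify at any time; PCI/CABG qualify only strictly beyond the
90-day blanking window ("within 90 days" = day ≤ 90 excluded). The earliest
qualifying event defines the endpoint; simultaneous events resolve with hard
events taking precedence over revascularization. Patients with blanked early
procedures remain in the risk set by default (the procedures, not the
patients, are excluded from the endpoint); a flag removes them entirely for
sensitivity analyses. Adjudication is order-invariant and, by construction,
widening the blanking window never adds events.

## Prognostic models

* **Fit**: Cox proportional hazards with an L1 penalty on the candidate
  covariates only (penalty factor 0 on age, sex, LGE), via coordinate
  descent (`sksurv` Coxnet, Breslow baseline). With no penalized covariates
  the model reduces to a plain maximum-partial-likelihood fit (lifelines,
  Efron ties). Simulated event times are continuous, so Breslow and Efron
  tie handling coincide on generated data. Penalized coefficients below
  1e-5 in absolute value are truncated to exactly zero so "selected out"
  is unambiguous.
* **Penalty selection**: 50 log-spaced penalties (down to 1e-3 of the
  data-derived maximum) scored on inner folds by cross-validated partial-
  likelihood deviance (Verweij–van Houwelingen form), with the one-
  standard-error rule: the largest penalty within one SE of the minimum
  mean deviance. The 1-SE rule is what makes the selection parsimonious
  enough to drop pure-noise covariates reliably.
* **Cross-validation**: outer folds (default 10) are event-stratified;
  each training fold re-selects its penalty, refits, and predicts held-out
  2-year event probabilities `1 − S₀(730 d)^exp(lp)` with the Breslow
  baseline from that training fold. Restarts repeat the whole loop with
  fresh fold assignments (500 in the motivating analysis; tests and the
  acceptance script use 1–3 restarts with 4–5 folds, sized for a single
  CPU — reported with their Monte-Carlo SE). All fold and restart
  randomness derives from one master seed.
* **Discrimination**: cumulative/dynamic time-dependent AUC at 730 days.
  Cases are events at or before the horizon (weight 1/G(T⁻)), controls are
  patients at risk beyond it (weight 1/G(h)), with G the Kaplan–Meier
  estimate of the censoring distribution; patients censored earlier get
  zero weight. The weighted ROC is integrated by trapezoid, which without
  censoring equals Mann–Whitney pairwise counting exactly (tested to 1e-9).
* **Risk categories**: <1% low, 1–3% intermediate (both boundaries
  inclusive), >3% high, applied to the 2-year out-of-fold probabilities.
  The guideline categories are annual; a scale factor is available if an
  annualized convention is preferred.
* **NRI/IDI**: categorical NRI
  `[P(up|event) − P(down|event)] + [P(down|nonevent) − P(up|nonevent)]`
  and IDI (between-model difference of mean predicted risk in events minus
  nonevents), both IPCW-weighted for censoring before the horizon;
  transition tables report raw classified counts.

## Known limitations

* Absolute MBF is in relative units and, under automatic delay estimation,
  biased upward (see above); only MPR is used downstream.
* The IPCW weights assume censoring independent of covariates; the
  synthetic generator satisfies this by construction.
* The lasso path is solved at a fixed grid; a penalty between grid points
  is never selected.
* The cohort generator draws event types independently of covariates, so
  subtype-specific analyses beyond counting are out of scope.
* Visual flags in the synthetic segment maps mirror ground truth; reader
  disagreement between visual and quantitative assessment is not modelled,
  so visual-vs-quantitative comparisons on synthetic data are optimistic
  for both.
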