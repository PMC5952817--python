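"""Synthetic perfusion curves, segment maps and survival cohorts.

The generators in this module produce data with the statistical structure the
analysis pipeline assumes, so every downstream stage can be exercised without
patient data:

* a gamma-variate bolus model for the arterial input function (AIF), with a
  1:10 diluted pre-bolus and a saturating main bolus mimicking the dual-bolus
  acquisition (0.0075 / 0.075 mmol/kg);
* tissue curves formed by convolving the true (unsaturated, full-dose) AIF
  with a Fermi impulse response at a known myocardial blood flow;
* 16-segment AHA maps subdivided into 32 endocardial/epicardial halves with
  controllable ischemic fraction and scar (LGE) prevalence;
* survival cohorts drawn from an exponential proportional-hazards model whose
  log-hazard is a linear predictor in age, sex, LGE and ischemic burden.

All randomness flows through ``numpy.random.default_rng`` seeds carried on the
spec objects, so equal seeds give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .perfusion import (
    DEFAULT_DOSE_RATIO,
    SignalCurve,
    convolve_impulse_response,
    fermi_impulse_response,
)

__all__ = [
    "AcquisitionSpec",
    "TissueGroundTruth",
    "CohortSpec",
    "generate_aif",
    "apply_saturation",
    "generate_tissue_curve",
    "generate_dual_bolus_study",
    "generate_segment_truth",
    "generate_cohort",
    "aha16_equal_masses",
    "DEFAULT_COEFFICIENTS",
]

# Gamma-variate bolus shape (first-pass kinetics): alpha controls wash-in
# sharpness, beta (seconds) the washout tail; peak occurs at alpha*beta after
# onset. Gain converts administered dose to peak signal units.
GAMMA_ALPHA = 3.0
GAMMA_BETA = 4.0
SIGNAL_GAIN = 2000.0  # signal-units at peak per mmol/kg

#: Ground-truth MPR sampling ranges: ischemic sub-segments sit clearly below
#: the 1.5 ischemia threshold, normal ones clearly above.
ISCHEMIC_MPR_RANGE = (0.5, 1.4)
NORMAL_MPR_RANGE = (1.8, 4.0)

#: Log-hazard coefficients of the quantitative-burden risk model used as the
#: cohort generator's default (age in years, sex 1=male, LGE 0/1, burden as a
#: fraction of myocardium).
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "age": 0.02,
    "sex": 2.722,
    "lge": 0.678,
    "burden": 2.490,
}

#: First-event type mix among endpoint events (late revascularization 39/52,
#: nonfatal MI 7/52, cardiovascular death 4/52, aborted sudden death 2/52).
EVENT_TYPE_PROBS: dict[str, float] = {
    "late_revasc": 39 / 52,
    "nonfatal_mi": 7 / 52,
    "cv_death": 4 / 52,
    "aborted_scd": 2 / 52,
}

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class AcquisitionSpec:
    """Sampling and contrast parameters of a simulated dual-bolus acquisition."""

    frame_interval: float = 1.0  # seconds
    n_frames: int = 60
    noise_sd: float = 0.0  # additive Gaussian, signal units
    prebolus_dose: float = 0.0075  # mmol/kg
    main_dose: float = 0.075  # mmol/kg
    saturation_ceiling: float = 80.0  # signal units
    dilution_factor: float = DEFAULT_DOSE_RATIO
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 20:
            raise ValueError("n_frames must be at least 20")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.prebolus_dose <= 0 or self.main_dose <= 0:
            raise ValueError("doses must be positive")
        if self.saturation_ceiling <= 0:
            raise ValueError("saturation_ceiling must be positive")
        ratio = self.main_dose / self.prebolus_dose
        if abs(ratio - self.dilution_factor) > 1e-9 * self.dilution_factor:
            raise ValueError(
                f"main_dose/prebolus_dose = {ratio:g} does not match the "
                f"dilution factor {self.dilution_factor:g}"
            )

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class TissueGroundTruth:
    """True Fermi impulse-response parameters for one simulated segment."""

    mbf_true: float
    r_true: float
    k_true: float
    tau0_true: float
    taud_true: float = 0.0

    def __post_init__(self) -> None:
        if self.mbf_true < 0 or self.r_true < 0 or self.k_true <= 0:
            raise ValueError("mbf_true and r_true must be >= 0, k_true positive")
        if self.tau0_true < 0 or self.taud_true < 0:
            raise ValueError("tau0_true and taud_true must be non-negative")
        implied = self.r_true / (np.exp(-self.tau0_true * self.k_true) + 1.0)
        if abs(implied - self.mbf_true) > 1e-6 * max(self.mbf_true, 1.0):
            raise ValueError(
                f"mbf_true={self.mbf_true:g} inconsistent with R={self.r_true:g}, "
                f"k={self.k_true:g}, tau0={self.tau0_true:g} (implies {implied:g})"
            )

    @classmethod
    def from_mbf(
        cls, mbf: float, k: float = 0.2, tau0: float = 3.0, taud: float = 0.0
    ) -> "TissueGroundTruth":
        """Build a truth whose amplitude R is consistent with the target MBF."""
        r = mbf * (np.exp(-tau0 * k) + 1.0)
        return cls(mbf_true=mbf, r_true=r, k_true=k, tau0_true=tau0, taud_true=taud)


def generate_aif(
    spec: AcquisitionSpec, dose: float, onset: float
) -> SignalCurve:
    """Noise-free gamma-variate arterial input curve for a given dose.

    The shape is ``((t-onset)/tp)^alpha * exp(alpha * (1 - (t-onset)/tp))``,
    peak-normalised to 1 at ``tp = alpha * beta`` past onset, scaled by
    ``dose * SIGNAL_GAIN``: zero before onset, single-peaked, and linear in
    dose (saturation is applied separately).
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    t = spec.t
    if not (t[0] <= onset <= t[-1]):
        raise ValueError("onset must lie within the sampled window")
    tp = GAMMA_ALPHA * GAMMA_BETA
    tau = np.maximum(t - onset, 0.0)
    shape = (tau / tp) ** GAMMA_ALPHA * np.exp(GAMMA_ALPHA * (1.0 - tau / tp))
    return SignalCurve(t=t, signal=dose * SIGNAL_GAIN * shape, region="AIF")


def apply_saturation(curve: SignalCurve, ceiling: float) -> SignalCurve:
    """Compress a curve through the saturating map ``s -> c*(1 - exp(-s/c))``.

    Monotone, bounded by the ceiling, and linear in the low-signal limit —
    the nonlinearity the dual-bolus pre-bolus scheme is designed to avoid.
    """
    if ceiling <= 0:
        raise ValueError("ceiling must be positive")
    return curve.with_signal(ceiling * (1.0 - np.exp(-curve.signal / ceiling)))


def generate_tissue_curve(
    aif: SignalCurve,
    truth: TissueGroundTruth,
    spec: AcquisitionSpec,
    rng: np.random.Generator | None = None,
) -> SignalCurve:
    """Tissue curve = rectangle-rule convolution of the AIF with the true
    Fermi impulse response, plus additive Gaussian noise of sd ``noise_sd``."""
    if len(aif.t) != spec.n_frames or abs(aif.dt - spec.frame_interval) > 1e-9:
        raise ValueError("AIF grid does not match the acquisition spec")
    t0 = aif.t - aif.t[0]
    h = fermi_impulse_response(
        t0, truth.r_true, truth.k_true, truth.tau0_true, truth.taud_true
    )
    clean = convolve_impulse_response(aif.signal, h, aif.dt)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
        clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    return SignalCurve(t=aif.t, signal=clean, region="tissue", phase=aif.phase)


def replace_noise_free(spec: AcquisitionSpec) -> AcquisitionSpec:
    """Copy of an acquisition spec with the noise turned off."""
    from dataclasses import replace

    return replace(spec, noise_sd=0.0)


def _segment_labels(n: int) -> list[str]:
    """Region labels 1_endo, 1_epi, 2_endo, ... for n sub-segments."""
    halves = ("endo", "epi")
    return [f"{i // 2 + 1}_{halves[i % 2]}" for i in range(n)]


def generate_dual_bolus_study(
    spec: AcquisitionSpec,
    truth_per_segment: Sequence[TissueGroundTruth],
    phase: str = "stress",
    patient_id: str = "P001",
    onset: float = 5.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one dual-bolus perfusion acquisition as a long curve table.

    Emits the diluted pre-bolus AIF (within the linear range, unsaturated),
    the saturated main-bolus AIF, and one tissue curve per supplied ground
    truth, driven by the true unsaturated full-dose AIF. Noise is additive
    Gaussian at a uniform signal-to-noise ratio across curves:
    ``spec.noise_sd`` is the noise sd on the strongest tissue curve (so the
    tissue SNR is peak signal / noise_sd), and every other curve receives
    noise scaled to its own peak, emulating the signal-adaptive gain and ROI
    averaging that keep the diluted pre-bolus measurement informative.
    """
    if len(truth_per_segment) == 0:
        raise ValueError("at least one segment ground truth is required")
    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng

    aif_true = generate_aif(spec, spec.main_dose, onset)
    aif_pre = generate_aif(spec, spec.prebolus_dose, onset)
    aif_main = apply_saturation(aif_true, spec.saturation_ceiling)

    clean_tissue = [
        generate_tissue_curve(aif_true, truth, replace_noise_free(spec))
        for truth in truth_per_segment
    ]
    peak_ref = max(float(np.max(c.signal)) for c in clean_tissue)

    def noisy(sig: np.ndarray) -> np.ndarray:
        if spec.noise_sd <= 0 or peak_ref <= 0:
            return sig
        sd = spec.noise_sd * float(np.max(np.abs(sig))) / peak_ref
        if sd <= 0:
            return sig
        return sig + rng.normal(0.0, sd, size=sig.shape)

    frames = []

    def emit(region: str, sig: np.ndarray) -> None:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": patient_id,
                    "region": region,
                    "phase": phase,
                    "t_seconds": spec.t,
                    "signal": sig,
                }
            )
        )

    emit("AIF_pre", noisy(aif_pre.signal))
    emit("AIF_main", noisy(aif_main.signal))
    for label, tis in zip(_segment_labels(len(truth_per_segment)), clean_tissue):
        emit(label, noisy(tis.signal))
    return pd.concat(frames, ignore_index=True)


def aha16_equal_masses() -> pd.Series:
    """Equal mass fractions over the 16 AHA segments (apical cap excluded)."""
    return pd.Series(np.full(16, 1.0 / 16.0), index=pd.RangeIndex(1, 17, name="aha_segment"))


def generate_segment_truth(
    n_ischemic: int,
    lge_segments: set[int] | frozenset[int] = frozenset(),
    mass_profile: pd.Series | None = None,
    patient_id: str = "P001",
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth 32-sub-segment map with a controllable ischemic count.

    Each of the 16 AHA segments is split into an endocardial and epicardial
    half; ``n_ischemic`` sub-segments are assigned a true MPR drawn from
    Uniform(0.5, 1.4) (below the 1.5 ischemia threshold) and the rest from
    Uniform(1.8, 4.0). Sub-segments of AHA segments in ``lge_segments`` carry
    the scar flag. Visual flags mirror the true ischemia status.
    """
    masses = aha16_equal_masses() if mass_profile is None else mass_profile
    if len(masses) != 16 or abs(float(masses.sum()) - 1.0) > 1e-9:
        raise ValueError("mass_profile must give 16 fractions summing to 1")
    if not 0 <= n_ischemic <= 32:
        raise ValueError("n_ischemic must lie in [0, 32]")
    bad = set(lge_segments) - set(range(1, 17))
    if bad:
        raise ValueError(f"invalid AHA segment ids in lge_segments: {sorted(bad)}")

    rng = np.random.default_rng(rng_seed)
    ischemic = np.zeros(32, dtype=bool)
    ischemic[rng.choice(32, size=n_ischemic, replace=False)] = True

    rows = []
    for i, label in enumerate(_segment_labels(32)):
        seg_str, half = label.rsplit("_", 1)
        seg = int(seg_str)
        lo, hi = ISCHEMIC_MPR_RANGE if ischemic[i] else NORMAL_MPR_RANGE
        rows.append(
            dict(
                patient_id=patient_id,
                aha_segment=seg,
                half=half,
                mass_fraction=float(masses.loc[seg]) / 2.0,
                lge=int(seg in lge_segments),
                visual_ischemic=int(ischemic[i]),
                mpr_true=float(rng.uniform(lo, hi)),
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic survival cohort.

    Covariates emulate the study population: age ~ Normal(58, 13) years, 70%
    male, 35.4% LGE-positive, and a zero-inflated-Beta ischemic burden (most
    patients have none; the affected minority averages ~19% of myocardium).
    Event times are exponential with hazard
    ``baseline_hazard_rate * exp(linear predictor)`` per person-year and
    independent exponential censoring.
    """

    n_patients: int = 395
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS)
    )
    baseline_hazard_rate: float = 0.0015  # events per person-year at lp = 0
    censoring_rate: float = 0.50  # per person-year; median follow-up ~460 d
    male_fraction: float = 0.70
    lge_prevalence: float = 0.354
    burden_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"p_zero": 0.55, "alpha": 1.2, "beta": 5.3}
    )
    early_revasc_fraction: float = 0.10  # procedures inside the 90-day window
    age_mean: float = 58.0
    age_sd: float = 13.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        if self.baseline_hazard_rate < 0 or self.censoring_rate < 0:
            raise ValueError("rates must be non-negative")
        for name, p in (
            ("male_fraction", self.male_fraction),
            ("lge_prevalence", self.lge_prevalence),
            ("early_revasc_fraction", self.early_revasc_fraction),
            ("p_zero", self.burden_distribution.get("p_zero", 0.0)),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a synthetic cohort table from a proportional-hazards model.

    Returns one row per patient with columns ``patient_id, age_years, sex,
    lge, visual_burden_fraction, mpr_burden_fraction, time_days, event,
    event_type, revasc_days`` (revascularization day offsets, semicolon
    separated; procedures inside the 90-day blanking window appear here and
    are not endpoint events). Reproducible: equal seeds give equal tables.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_patients

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 95.0)
    sex = (rng.random(n) < spec.male_fraction).astype(int)
    lge = (rng.random(n) < spec.lge_prevalence).astype(int)

    bd = spec.burden_distribution
    nonzero = rng.random(n) >= bd["p_zero"]
    burden = np.where(nonzero, rng.beta(bd["alpha"], bd["beta"], n), 0.0)
    # visual read of the same underlying ischemia, with reader noise
    visual = np.clip(burden * rng.uniform(0.7, 1.3, n)
                     + np.where(burden > 0, rng.normal(0.0, 0.02, n), 0.0), 0.0, 1.0)

    coef = spec.coefficients
    lp = (
        coef.get("age", 0.0) * age
        + coef.get("sex", 0.0) * sex
        + coef.get("lge", 0.0) * lge
        + coef.get("burden", 0.0) * burden
    )
    hazard = spec.baseline_hazard_rate * np.exp(lp)  # per person-year
    with np.errstate(divide="ignore"):
        t_event_years = np.where(
            hazard > 0, rng.exponential(1.0, n) / np.maximum(hazard, 1e-300), np.inf
        )
        t_cens_years = np.where(
            spec.censoring_rate > 0,
            rng.exponential(1.0 / max(spec.censoring_rate, 1e-300), n),
            np.inf,
        )
    # administrative cap keeps follow-up finite even with no censoring process
    t_cens_years = np.minimum(t_cens_years, 6.0)
    time_years = np.minimum(t_event_years, t_cens_years)
    event = (t_event_years <= t_cens_years).astype(int)
    time_days = np.maximum(np.round(time_years * DAYS_PER_YEAR), 1.0)

    types = list(EVENT_TYPE_PROBS)
    probs = np.array([EVENT_TYPE_PROBS[t] for t in types])
    event_type = np.where(
        event == 1, rng.choice(types, size=n, p=probs), "censored"
    ).astype(object)
    # a late-revascularization first event cannot occur inside the blanking
    # window; push those few event times just past it
    is_revasc = (event == 1) & (event_type == "late_revasc")
    time_days = np.where(is_revasc & (time_days <= 90), 91.0, time_days)

    revasc_days: list[str] = []
    early = rng.random(n) < spec.early_revasc_fraction
    for i in range(n):
        days: list[int] = []
        if early[i] and time_days[i] > 5:
            days.append(int(rng.integers(5, min(90, int(time_days[i])) + 1)))
        if is_revasc[i]:
            days.append(int(time_days[i]))
        revasc_days.append(";".join(str(d) for d in sorted(days)))

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:05d}" for i in range(n)],
            "age_years": age,
            "sex": sex,
            "lge": lge,
            "visual_burden_fraction": visual,
            "mpr_burden_fraction": burden,
            "time_days": time_days.astype(float),
            "event": event,
            "event_type": event_type,
            "revasc_days": revasc_days,
        }
    )
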