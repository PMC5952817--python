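import numpy as np
import pytest

from cmrperf import synthetic as sy


@pytest.fixture(scope="session")
def acq_spec():
    """Noise-free dual-bolus acquisition at 1 s / 60 frames."""
    return sy.AcquisitionSpec()


@pytest.fixture(scope="session")
def main_aif(acq_spec):
    """True (unsaturated) full-dose arterial input, onset 5 s."""
    return sy.generate_aif(acq_spec, acq_spec.main_dose, onset=5.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 400-patient synthetic cohort under the default model."""
    return sy.generate_cohort(sy.CohortSpec(n_patients=400, rng_seed=11))


@pytest.fixture(scope="session")
def analysis_table(small_cohort):
    """Cohort table renamed to the covariate names the risk models use."""
    df = small_cohort.rename(
        columns={
            "age_years": "age",
            "visual_burden_fraction": "visual_burden",
            "mpr_burden_fraction": "mpr_burden",
        }
    ).copy()
    df["mpr_positive"] = (df["mpr_burden"] >= 0.10).astype(int)
    df["visual_positive"] = (df["visual_burden"] >= 2 / 16).astype(int)
    return df
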