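import numpy as np
import pandas as pd
import pytest

from cohortpath.qc import derive_bmi_columns
from cohortpath.simulate import ScenarioConfig, simulate_cohort
from cohortpath.survey import SurveyDesign


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scenario cohort (10 strata x 4 PSUs x 100) with BMI columns."""
    df = simulate_cohort(ScenarioConfig(seed=42))
    df, _ = derive_bmi_columns(df, apply_bounds=False)
    return df


@pytest.fixture(scope="session")
def default_design(default_cohort):
    return SurveyDesign.from_frame(default_cohort)


def recovery_cohort(seed: int, persons_per_psu: int = 1250) -> pd.DataFrame:
    """Noise-free-recall, equal-weight cohort for parameter-recovery checks.

    Recall noise exists to exercise QC; as measurement error on mediator BMIs
    it attenuates downstream coefficients, so recovery of the generative DAG
    is assessed on noise-free self-reports.
    """
    cfg = ScenarioConfig(
        seed=seed,
        persons_per_psu=persons_per_psu,
        equal_weights=True,
        recall_noise_sd=0.0,
    )
    df = simulate_cohort(cfg)
    df, _ = derive_bmi_columns(df, apply_bounds=False)
    return df
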