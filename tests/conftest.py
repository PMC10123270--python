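import pandas as pd
import pytest

from axilen import GeneratorConfig, StiffnessElongationModel, calibrate_generator, generate_cohort

#: Cohort size / seed used for all parameter-recovery checks.
RECOVERY_N = 5000
RECOVERY_SEED = 101


@pytest.fixture(scope="session")
def recovery_config() -> GeneratorConfig:
    """Default calibrated generator at the parameter-recovery size."""
    return calibrate_generator(GeneratorConfig(n=RECOVERY_N, seed=RECOVERY_SEED))


@pytest.fixture(scope="session")
def recovery_cohort(recovery_config) -> pd.DataFrame:
    return generate_cohort(recovery_config)


@pytest.fixture(scope="session")
def recovery_results(recovery_cohort):
    return StiffnessElongationModel(recovery_cohort).fit()


@pytest.fixture()
def toy_cohort() -> pd.DataFrame:
    """Tiny hand-written cohort with plausible clinical values."""
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(1, 11)],
            "eye": ["OD"] * 10,
            "age": [18, 22, 25, 30, 19, 21, 24, 28, 35, 20],
            "gender": ["female", "male"] * 5,
            "ser_d": [-2.0, -6.5, -1.0, -8.0, -3.5, -5.0, -0.5, -7.25, -4.0, -6.0],
            "ssi": [0.95, 0.70, 1.05, 0.62, 0.88, 0.75, 1.10, 0.66, 0.80, 0.72],
            "cct_um": [540, 520, 560, 510, 545, 535, 570, 505, 550, 530],
            "cr_mm": [7.9, 7.6, 8.0, 7.5, 7.8, 7.7, 8.1, 7.55, 7.85, 7.65],
            "al_mm": [24.5, 26.8, 24.0, 27.5, 25.2, 26.0, 23.8, 27.2, 25.5, 26.5],
        }
    )
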