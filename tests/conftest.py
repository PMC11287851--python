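import numpy as np
import pytest

from famine_metabosig.exposure import classify_cohort
from famine_metabosig.pipeline import preprocess_matrix
from famine_metabosig.synthetic import SimConfig, generate_study


def small_config(**overrides) -> SimConfig:
    """Desk-scale simulation design used by the fast tests.

    240 + 232 participants and a 24-biomarker panel in two correlated
    blocks keep each GEE fit and PCA cheap while preserving the study's
    statistical structure (sibships, BMI axis, mediated effects).
    """
    base = dict(
        n_exposed=240,
        n_control=232,
        n_biomarkers=24,
        block_structure=[(12, 0.9), (12, 0.9)],
        target_pc95=2,
        n_diseases=60,
        n_lod_biomarkers=4,
        n_zero_biomarkers=2,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def small_analysis(small_study):
    """Classified, preprocessed desk-scale study ready for modelling."""
    cohort = classify_cohort(small_study.cohort)
    cohort, matrix, _ = preprocess_matrix(cohort, small_study.biomarkers)
    return cohort, matrix, small_study


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
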