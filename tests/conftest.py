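import numpy as np
import pytest

from neurocpm import CohortSpec, CohortTable, MODALITIES, generate_cohort
from neurocpm.pipeline import PipelineConfig, build_cohort_table


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three subjects, 20 s — fast signal-level cohort for structural checks."""
    spec = CohortSpec(n_subjects=3, duration_s=20.0, seed=5)
    subjects, gt = generate_cohort(spec)
    return spec, subjects, gt


@pytest.fixture(scope="session")
def recovery_table():
    """Full signal-level pipeline on a 30-subject cohort with a strong
    planted effect (effect_r = 0.8); shared across the recovery checks
    because feature extraction dominates the cost."""
    spec = CohortSpec(n_subjects=30, seed=11, effect_r=0.8)
    config = PipelineConfig(cohort=spec)
    table, gt = build_cohort_table(config)
    return table, gt


def random_cohort_table(rng, n_subjects=10, n_eeg=4, n_fnirs=6):
    """Arbitrary valid CohortTable with random symmetric matrices."""
    def sym(n):
        a = rng.uniform(-1, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        return a

    matrices = {}
    for mod in MODALITIES:
        n = n_eeg if "m_" in mod else n_fnirs
        matrices[mod] = np.stack([sym(n) for _ in range(n_subjects)])
    return CohortTable(
        subject_ids=[f"s{i}" for i in range(n_subjects)],
        matrices=matrices,
        performance=rng.uniform(10, 90, n_subjects))
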