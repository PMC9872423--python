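import numpy as np
import pytest

from deepradiomics.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests (16x16 slices)."""
    cfg = SimConfig(n_patients=20, images_per_patient_range=(2, 5),
                    image_size=16, n_risk_genes=30, n_planted_genes=6,
                    effect_size=1.0, n_pathways=5, pathway_size_range=(3, 10),
                    seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
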