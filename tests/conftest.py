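import numpy as np
import pytest
from hypothesis import settings

from pcr_radiomics.imaging_io import ImageVolume, ROIMask
from pcr_radiomics.model import default_model_spec
from pcr_radiomics.synthetic_data import CohortSpec, sample_cohort

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model_spec():
    return default_model_spec()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_volume(rng):
    """A 12x12x6 float volume with rectal-T2-like anisotropic spacing."""
    vox = 100.0 + 5.0 * rng.standard_normal((12, 12, 6))
    return ImageVolume(voxels=vox, spacing=(0.5, 0.5, 3.0))


@pytest.fixture
def small_mask(small_volume):
    m = np.zeros(small_volume.shape, dtype=bool)
    m[3:9, 3:9, 1:5] = True
    return ROIMask(voxels=m, spacing=small_volume.spacing)


@pytest.fixture(scope="session")
def tabular_cohort(model_spec):
    """A 2000-patient tabular cohort with model-generated labels."""
    table, _ = sample_cohort(CohortSpec(n=2000, seed=11), model_spec)
    return table.df


@pytest.fixture(scope="session")
def validation_like_cohort(model_spec):
    """59 patients, exactly 10 pCR, matching the validation-cohort margins."""
    spec = CohortSpec(n=59, label_mode="fixed-prevalence", n_positive=10, seed=42)
    table, _ = sample_cohort(spec, model_spec)
    return table.df
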