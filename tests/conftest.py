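import numpy as np
import pytest
from dataclasses import replace

from isatlas.core import SpecimenSet
from isatlas.phantoms import PhantomSpec, make_cohort, make_template
from isatlas.preprocess import apply_mask, normalize_intensity


@pytest.fixture(scope="session")
def clean_spec_32():
    """Noise- and warp-free phantom spec on a 32³ grid (fast sanity checks)."""
    return replace(PhantomSpec().scaled(32), noise_sd=0.0, warp_sd_vox=0.0, n_muscle_blobs=2)


@pytest.fixture(scope="session")
def template_32(clean_spec_32):
    return make_template(clean_spec_32)


@pytest.fixture(scope="session")
def template_64_clean():
    spec = replace(PhantomSpec().scaled(64), noise_sd=0.0, warp_sd_vox=0.0)
    return spec, make_template(spec)


@pytest.fixture(scope="session")
def masked_cohort_48():
    """Default-condition 4-specimen cohort at 48³, preprocessed for ISA."""
    spec = PhantomSpec().scaled(48)
    cohort, truth = make_cohort(spec, 4, seed=1)
    masked = SpecimenSet(
        [apply_mask(v, m) for v, m in zip(cohort.volumes, truth.specimen_masks)],
        cohort.labels,
        cohort.ids,
    )
    masked = SpecimenSet(
        [normalize_intensity(v) for v in masked.volumes], masked.labels, masked.ids
    )
    return masked, truth


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
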