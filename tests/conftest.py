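import numpy as np
import pytest

from twopac import AssayDesign, ModelParams, sample_cohort


@pytest.fixture(scope="session")
def ref_params() -> ModelParams:
    """Parameter set fitted to the reference 1146-fly female cohort
    (hazard slope 0.0039/day^2, intercept -0.019/day, phase-2 death
    rate 0.1911/day)."""
    return ModelParams(a=0.0039, b=-0.019, k=0.1911)


@pytest.fixture(scope="session")
def ref_cohort(ref_params):
    """One fixed-seed synthetic cohort at the reference size (n=1146)."""
    design = AssayDesign(n_individuals=1146, n_vials=4, seed=20150)
    return sample_cohort(ref_params, design)


@pytest.fixture(scope="session")
def daily_ages():
    return np.arange(0.0, 90.0)
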