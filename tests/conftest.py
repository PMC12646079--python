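import numpy as np
import pytest

from neuroperm import SimulationConfig, make_cohort
from neuroperm.connectivity import FcMatrix, fisher_z


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_config():
    """Tiny but full-structure study: 2 subjects per genotype-sex cell."""
    return SimulationConfig(n_per_cell=2, n_timepoints_scan=120, seed=7)


@pytest.fixture()
def cohort(small_config):
    return make_cohort(small_config)


def random_fc(rng, r=36, scale=0.3, **meta) -> FcMatrix:
    """A random but valid Fisher-z connectivity matrix."""
    from neuroperm.parcellation import DEFAULT_ROI_NAMES

    x = rng.standard_normal((r + 10, r))
    corr = np.corrcoef(x, rowvar=False)
    names = list(DEFAULT_ROI_NAMES) if r == 36 else None
    return fisher_z(corr * scale + np.eye(r) * (1 - scale), roi_names=names,
                    **meta)


@pytest.fixture()
def fc36(rng):
    return random_fc(rng)
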