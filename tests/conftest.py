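import dataclasses

import numpy as np
import pytest

from olfnet import (DynamicsConfig, MothTemplate, generate_moth,
                    make_default_template)
from olfnet.stimuli import build_learning_schedule, odor_maps_for


@pytest.fixture(scope="session")
def small_template() -> MothTemplate:
    """Scaled-down moth for fast dynamics tests (20 glomeruli, 240 KCs)."""
    return MothTemplate(n_glomeruli=20, n_kc=240, n_qn=5, kc_degree=6,
                        qn_degree=7, hits_per_odor=7, lh_inhibition=34.0)


@pytest.fixture(scope="session")
def small_moth(small_template):
    return generate_moth(small_template, seed=2)


@pytest.fixture(scope="session")
def small_setup(small_template, small_moth):
    """Moth + config + 2 odor maps + a short 1-session learning schedule."""
    cfg = DynamicsConfig.from_template(small_template)
    maps = odor_maps_for(small_template, 2, np.random.default_rng(3))
    sched = build_learning_schedule(2, 0, 2, dt=cfg.dt, odor_maps=maps,
                                    baseline_stims=4, post_stims=4)
    return small_moth, cfg, maps, sched


@pytest.fixture(scope="session")
def default_template() -> MothTemplate:
    return make_default_template()


def quiet_template(template: MothTemplate) -> MothTemplate:
    """Variant with Hebbian growth disabled."""
    return dataclasses.replace(template, gamma_pk=0.0, gamma_qk=0.0,
                               gamma_ke=0.0)
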