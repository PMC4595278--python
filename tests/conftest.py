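import numpy as np
import pytest

from racert.race_algebra import equality_catalog
from racert.synthetic_observer import default_mapping, sample_rts, scenario_preset


@pytest.fixture(scope="session")
def catalog():
    return equality_catalog()


@pytest.fixture(scope="session")
def no_conjunction_model():
    return scenario_preset("no_conjunction")


@pytest.fixture(scope="session")
def v1_like_model():
    return scenario_preset("v1_like")


def rt_samples(model, types, n, seed):
    """Per-type RT samples from a preset under its calibrated mapping."""
    mapping = default_mapping(model)
    rng = np.random.default_rng(seed)
    return {t: sample_rts(model, mapping, t, n, rng) for t in types}


@pytest.fixture()
def re2_null_samples(no_conjunction_model, catalog):
    """150 RTs per type for RE2 from a generator that satisfies it exactly."""
    return rt_samples(no_conjunction_model, catalog["RE2"].all_types, 150, seed=11)
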