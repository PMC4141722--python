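import dataclasses

import pytest

import ioniccable as ic


@pytest.fixture(scope="session")
def model():
    """The shipped default model."""
    return ic.build_model()


@pytest.fixture(scope="session")
def geometry(model):
    return model.geometry


@pytest.fixture(scope="session")
def passive_model(model):
    """Default model with every hotspot strength and the NMDA count zeroed."""
    m = dataclasses.replace(model)
    m.channels = {k: v.scaled(0.0) for k, v in model.channels.items()}
    m.nmda = dataclasses.replace(model.nmda, count=0.0)
    return m


@pytest.fixture(scope="session")
def cache(model):
    return ic.KernelCache(model.geometry, model.dt_ms)
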