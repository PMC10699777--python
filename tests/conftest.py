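import pytest

from n2opulse import default_config


@pytest.fixture()
def cfg():
    """Default run configuration (worked-example apparatus, seed 0)."""
    return default_config(seed=0)


@pytest.fixture()
def geom(cfg):
    return cfg.chamber_geometry
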