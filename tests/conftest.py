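import pytest

from triodx import synthetic


@pytest.fixture(scope="session")
def scene(tmp_path_factory):
    """Default 22-gene synthetic trio scene, fully written to disk."""
    return synthetic.make_default_scene(tmp_path_factory.mktemp("scene"), seed=7)


@pytest.fixture(scope="session")
def genome(scene):
    return scene.genome


@pytest.fixture(scope="session")
def truth(scene):
    return scene.truth
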