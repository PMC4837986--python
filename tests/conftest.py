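import pytest


@pytest.fixture(autouse=True)
def isolated_cache(tmp_path, monkeypatch):
    """Keep template/gold-standard caches inside the test tmp dir."""
    monkeypatch.setenv("DREAMBENCH_CACHE", str(tmp_path / "cache"))
    yield


@pytest.fixture
def registry():
    from dreambench import default_registry

    return default_registry()
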