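import pytest

from aremotif import load_probe_panel


@pytest.fixture(scope="session")
def probe_panel():
    return load_probe_panel()


@pytest.fixture(scope="session")
def probe_by_name(probe_panel):
    return {p.name: p for p in probe_panel}
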