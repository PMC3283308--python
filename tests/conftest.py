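import pytest

from dedouble.simulate import worked_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Named worked-example genomes (E1..E6 and the published 26-marker one)."""
    return worked_fixtures()
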