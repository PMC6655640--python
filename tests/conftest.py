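import pytest

from mycovir.rdrp_screen import default_models


@pytest.fixture(scope="session")
def models():
    """Calibrated bundled profiles (calibration is the slow step; share it)."""
    return default_models()
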