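import numpy as np
import pytest

from helixcrypt import EncryptionConfig, derive_master_key

#: low KDF cost for the experiment harness; hardness is orthogonal to
#: everything measured here
FAST_KDF = 1000


@pytest.fixture(scope="session")
def fast_config():
    return EncryptionConfig(kdf_iterations=FAST_KDF)


@pytest.fixture(scope="session")
def key():
    """One deterministic key shared by tests that only need *a* key."""
    return derive_master_key("test-passphrase", bytes(range(16)), FAST_KDF)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
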