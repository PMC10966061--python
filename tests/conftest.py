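import numpy as np
import pytest

from ronisteg import (
    EmbeddingKey,
    PhantomSpec,
    adjust_message,
    blockify_message,
    generate_patient_record,
    generate_phantom,
    text_to_qr,
    threshold_mask,
)


@pytest.fixture(scope="session")
def ct_phantom():
    """One CT-style 512x512 16-bit phantom with its ground-truth mask."""
    return generate_phantom(PhantomSpec.ct(seed=11))


@pytest.fixture(scope="session")
def mr_phantom():
    """One MR-style 256x256 12-bit phantom with its ground-truth mask."""
    return generate_phantom(PhantomSpec.mr(seed=12))


@pytest.fixture(scope="session")
def ct_mask(ct_phantom):
    return threshold_mask(ct_phantom[0])


@pytest.fixture(scope="session")
def mr_mask(mr_phantom):
    return threshold_mask(mr_phantom[0])


@pytest.fixture(scope="session")
def record():
    return generate_patient_record(11)


@pytest.fixture(scope="session")
def message_blocks(record):
    return blockify_message(adjust_message(text_to_qr(record)))


@pytest.fixture()
def key1000():
    return EmbeddingKey(beta=1000)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
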