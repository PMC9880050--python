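import numpy as np
import pytest

from fpmnet import SampleRecord, SyntheticParams, generate_sample
from fpmnet.config import NetworkConfig, small_config


def synth_records(n, size, seed0, split="train"):
    """Generate n in-memory synthetic records at the given canvas size."""
    recs = []
    for s in range(n):
        p = SyntheticParams(seed=seed0 + s, height=size, width=size,
                            fov_margin=max(3, size // 42),
                            width_root=3.5 if size <= 64 else 4.5)
        img, mask = generate_sample(p)
        recs.append(SampleRecord(id=f"{split}{s:03d}", image=img, mask=mask,
                                 split=split))
    return recs


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest non-trivial config: cheap builds for contract tests."""
    return NetworkConfig(
        input_height=32, input_width=32, fdb_blocks=3,
        fdb_channel_schedule=[4, 8, 8], convs_per_block=2, pooling_ops=2,
        fub_channel_schedule=[8, 4], fpb_channels=4, fif_channels=4,
        depthwise_separable_from_block=2)


@pytest.fixture(scope="session")
def small_net_config():
    return small_config(64)


@pytest.fixture(scope="session")
def tiny_records():
    """Tiny 24x24 records for augmentation count tests."""
    rng = np.random.default_rng(0)
    recs = []
    for i in range(20):
        img = rng.random((24, 24, 3)).astype(np.float32)
        mask = (rng.random((24, 24)) > 0.9).astype(np.uint8)
        recs.append(SampleRecord(id=f"im{i:02d}", image=img, mask=mask))
    return recs
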