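import numpy as np
import pytest

from pcgvit import BranchConfig, ModelConfig, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """A miniature two-stream config for fast structural/gradient tests."""
    return ModelConfig(
        branch_small=BranchConfig(patch_size=16, embed_dim=16, depth=1, heads=2, mlp_hidden=32),
        branch_large=BranchConfig(patch_size=32, embed_dim=16, depth=1, heads=2, mlp_hidden=32),
        n_classes=2,
        classifier_hidden=(16, 16),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """12 subjects × 2 short recordings, strongly separable classes."""
    cfg = SynthConfig(n_subjects=12, records_per_subject=2,
                      duration_range=(5.0, 6.0), murmur_snr_db=10.0, seed=42)
    return cfg, generate_dataset(cfg)
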