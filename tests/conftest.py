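import numpy as np
import pytest

from telosig.synthetic_data import SyntheticConfig


def small_config(**overrides) -> SyntheticConfig:
    """A scaled-down generator configuration for fast unit tests."""
    base = dict(
        n_background_genes=200,
        n_focal_chrom_genes=80,
        n_housekeeping=8,
        n_planted_up=4,
        n_planted_down=6,
        n_marker_genes_per_type=4,
        replicates_per_sample_group=3,
        effect_ratio=3.0,
        noise_sigma=0.0,
        seed=11,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_dataset():
    """Noiseless small dataset: (matrix, annotation, metadata, truth)."""
    from telosig.synthetic_data import generate_dataset
    return generate_dataset(small_config())
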