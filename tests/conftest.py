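import numpy as np
import pandas as pd
import pytest

from mbomics import SimConfig, generate_multiblock


@pytest.fixture(scope="session")
def small_study():
    """A compact four-block case/control dataset with planted signal."""
    cfg = SimConfig(
        n_case=40,
        n_control=44,
        block_specs=[
            ("lipidomics_pos", 30, 2),
            ("lipidomics_neg", 20, 2),
            ("metabolomics_pos", 25, 2),
            ("metabolomics_neg", 15, 2),
        ],
        effect_size=2.0,
        within_subject_repeats=4,
        missing_rate=0.02,
        zero_rate=0.01,
        qc_count=5,
        seed=11,
    )
    return generate_multiblock(cfg)


@pytest.fixture()
def autoscaled_frame():
    """Seeded autoscaled random matrix for model-level unit tests."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(60, 12))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return pd.DataFrame(X, columns=[f"a{j}" for j in range(12)])
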