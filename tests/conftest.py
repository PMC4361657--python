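import numpy as np
import pytest

from tolerograph import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """One moderately sized dataset with all planted categories."""
    cfg = SimConfig(
        n_probes=1000, n_tol_up=30, n_tol_down=30, n_ntol_up=15,
        n_ntol_down=15, n_confounded=60, effect_log2=1.0,
        sd_range=(0.4, 0.4), seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Pure-null dataset: every probe NULL."""
    cfg = SimConfig(n_probes=500, n_tol_up=0, n_tol_down=0, n_ntol_up=0,
                    n_ntol_down=0, n_confounded=0, seed=13)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
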