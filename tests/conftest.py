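import numpy as np
import pytest

from xspecies.synth import SimConfig, TemporalSpec, inject_artifacts, simulate_dataset


@pytest.fixture(scope="session")
def sim_default():
    """Default study conditions, no injected artifacts."""
    cfg = SimConfig(seed=0)
    cc, ch, meta, orth, truth = simulate_dataset(cfg)
    return cfg, cc, ch, meta, orth, truth


@pytest.fixture(scope="session")
def sim_artifacts():
    """Default study conditions with injected doublets and low-quality cells."""
    cfg = SimConfig(seed=0)
    cc, ch, meta, orth, truth = simulate_dataset(cfg)
    cms, meta, truth = inject_artifacts({"cyno": cc, "human": ch}, meta, cfg, truth)
    return cfg, cms, meta, orth, truth


@pytest.fixture(scope="session")
def sim_small():
    """Compact dataset for fast unit tests: 3 cell types, fewer genes."""
    cts = [("T", 40), ("B", 40), ("Mono", 40)]
    cfg = SimConfig(
        seed=11, n_genes=200, cell_types=cts,
        temporal={n: TemporalSpec(n_affected=50, effect_size=1.2, cosine=0.8)
                  for n, _ in cts},
        lr_truth=[],
    )
    cc, ch, meta, orth, truth = simulate_dataset(cfg)
    return cfg, cc, ch, meta, orth, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
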