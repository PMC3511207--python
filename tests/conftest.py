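import pytest

from pinpi.annotate import annotate_precursor
from pinpi.io import load_reference_table
from pinpi.synth import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def reference_table():
    """The packaged 47-gene composition / clone-count table."""
    return load_reference_table()


@pytest.fixture(scope="session")
def small_dataset():
    """One small noise-free synthetic dataset with its annotations."""
    cfg = SyntheticConfig(seed=42, n_genes=15, n_unique_irds=12, n_cys_variants=2)
    ds = simulate(cfg)
    acfg = cfg.annotation_config()
    annotations = [annotate_precursor(r, acfg) for r in ds.precursors]
    return cfg, ds, annotations
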