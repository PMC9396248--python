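import numpy as np
import pytest

from ileumatlas import synthetic_data as sd


@pytest.fixture(scope="session")
def small_atlas():
    """Six-sample atlas at reduced size with doublets and low-quality cells."""
    cfg = sd.ileum_default_config(n_cells_per_sample=250, seed=1)
    adata, truth = sd.generate_atlas(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def clean_five_type():
    """Tight five-type dataset without doublets/low-quality cells, sized so
    graph clustering can resolve the types exactly."""
    types = ["B", "CD4_T", "CD8_T", "ILC", "epithelial"]
    comp = {t: 0.2 for t in types}
    cfg = sd.ileum_default_config(n_cells_per_sample=150, seed=7)
    cfg.samples = [
        sd.SampleSpec("s1", "a1", "ileum", dict(comp)),
        sd.SampleSpec("s2", "a2", "ileum", dict(comp)),
        sd.SampleSpec("s3", "a1", "ileum", dict(comp)),
    ]
    cfg.doublet_rate = 0.0
    cfg.lowq_rate = 0.0
    cfg.dirichlet_concentration = 40.0
    adata, truth = sd.generate_atlas(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def two_tissue():
    """Gut + blood pair sharing ILC and CD4_T with planted tissue blocks;
    B is gut-exclusive and myeloid blood-exclusive."""
    cfg = sd.ileum_default_config(n_cells_per_sample=400, seed=5)
    cfg.samples = [
        sd.SampleSpec("il1", "a1", "ileum", {"ILC": 0.4, "CD4_T": 0.3, "B": 0.3}),
        sd.SampleSpec("pb1", "a1", "pbmc", {"ILC": 0.5, "CD4_T": 0.3, "myeloid": 0.2}),
    ]
    cfg.doublet_rate = 0.0
    cfg.lowq_rate = 0.0
    a, b, ta, tb = sd.generate_two_tissue(
        cfg,
        shared_types=["ILC", "CD4_T"],
        exclusive_types={"ileum": ["B"], "pbmc": ["myeloid"]},
    )
    return cfg, a, b, ta, tb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
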