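import numpy as np
import pytest

from mkcobind.simulate import (LandscapeConfig, generate_gene_models,
                               generate_histone_and_expression,
                               generate_peak_landscape)


@pytest.fixture(scope="session")
def default_landscape():
    """One default-config synthetic landscape shared across tests."""
    cfg = LandscapeConfig(seed=11)
    genes = generate_gene_models(cfg)
    peaksets, truth = generate_peak_landscape(cfg, genes)
    marks, expression, truth = generate_histone_and_expression(cfg, genes, truth)
    return dict(config=cfg, genes=genes, peaksets=peaksets, marks=marks,
                expression=expression, truth=truth)


def small_config(seed: int, **overrides) -> LandscapeConfig:
    """A tiny landscape (<=1e5 bp genome) for brute-force oracle checks."""
    defaults = dict(
        seed=seed,
        chrom_sizes={"chrA": 50_000, "chrB": 50_000},
        n_genes=20,
        gene_length=(1_000, 4_000),
        min_gene_gap=500,
        marginal_targets={"GATA1": 8, "GATA2": 6, "RUNX1": 10, "FLI1": 12, "SCL": 7},
        n_complex_regions=2,
        n_background_sites=30,
        min_site_spacing=1_500,
        universe_n=500,
    )
    defaults.update(overrides)
    return LandscapeConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
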