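import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from plastiqtl.simulate import (SimConfig, TraitArchitecture, TraitSpec,
                                QTLSpec, simulate_map_and_genotypes,
                                simulate_phenotypes)


@pytest.fixture(scope="session")
def small_population():
    """A 3-chromosome, 200-line RIL population with a clean map."""
    cfg = SimConfig(n_lines=200, n_chromosomes=3,
                    chrom_lengths_cM=[100.0, 80.0, 60.0],
                    chrom_names=["1A", "2A", "3A"],
                    marker_spacing_cM=5.0, seed=11)
    map_df, geno = simulate_map_and_genotypes(cfg)
    return cfg, map_df, geno


@pytest.fixture(scope="session")
def phenotyped_population(small_population):
    """The small population with a two-QTL trait architecture."""
    cfg, map_df, geno = small_population
    arch = TraitArchitecture(
        traits=[
            TraitSpec("DP-H", "phenology", 55.0, 0.0, {"WW": 1.0, "WL": 1.0}),
            TraitSpec("GY", "yield", 20.0, -0.5, {"WW": 1.0, "WL": 1.0}),
            TraitSpec("TKW", "yield", 35.0, 0.0, {"WW": 1.0, "WL": 1.0}),
        ],
        qtls=[
            QTLSpec("DP-H", "1A", 50.0, -1.0, -1.5),
            QTLSpec("TKW", "2A", 40.0, 1.0, 1.0),
            QTLSpec("GY", "3A", 30.0, 0.0, 1.2),
        ])
    table, truth = simulate_phenotypes(map_df, geno, arch, cfg)
    return cfg, map_df, geno, arch, table, truth


def ols_oracle(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Independent normal-equations solver: residuals of y on [1, X]."""
    Z = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
    return y - Z @ beta
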