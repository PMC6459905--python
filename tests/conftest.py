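import numpy as np
import pandas as pd
import pytest

from exoburden.io import GenotypeStudy
from exoburden.simulate import SimulationConfig, simulate_study


def make_study(genotypes, phenotype, **variant_cols):
    """Assemble a GenotypeStudy from raw arrays (tests' building block)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "phenotype": np.asarray(phenotype, dtype=np.int8),
            "sex": 1,
            "country": "NL",
        }
    )
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": variant_cols.pop("chrom", [1] * m),
            "pos": variant_cols.pop("pos", np.arange(1, m + 1) * 1000),
            "a1": variant_cols.pop("a1", ["A"] * m),
            "a2": variant_cols.pop("a2", ["G"] * m),
        }
    )
    for name, values in variant_cols.items():
        variants[name] = values
    return GenotypeStudy(g, samples, variants)


@pytest.fixture(scope="session")
def small_null_study():
    """A modest null study shared by read-only tests."""
    cfg = SimulationConfig(
        n_cases=150, n_controls=150, n_countries=2, n_genes=60,
        variants_per_gene=8, singleton_reference_n=300,
        maf_spectrum=(0.3, 0.2, 0.2, 0.2, 0.1), seed=11,
    )
    return simulate_study(cfg)
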