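import numpy as np
import pandas as pd
import pytest

from divpanel.formats_io import DistanceMatrix, GenotypeMatrix, PhenotypeTable
from divpanel.synthetic_panel import PanelConfig, generate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_panel():
    """60 accessions in 3 groups, 500 SNPs, strong trait separation."""
    cfg = PanelConfig(n_accessions=60, n_groups=3, group_sizes=(20, 20, 20),
                      n_snps=500, seed=7)
    gm, pheno, records, truth = generate_panel(cfg)
    return cfg, gm, pheno, records, truth


@pytest.fixture
def random_genotypes(rng):
    """15 accessions x 40 loci, no missing, complete dosage matrix."""
    dosage = rng.integers(0, 3, size=(15, 40)).astype(np.int8)
    ids = [f"A{i:02d}" for i in range(15)]
    loci = [f"L{j:02d}" for j in range(40)]
    return GenotypeMatrix(ids, loci, dosage)


@pytest.fixture
def random_numeric_pheno(rng):
    """15 accessions x 8 quantitative traits."""
    ids = [f"A{i:02d}" for i in range(15)]
    data = pd.DataFrame(rng.normal(size=(15, 8)),
                        index=ids, columns=[f"t{j}" for j in range(8)])
    return PhenotypeTable(data, {f"t{j}": "quantitative" for j in range(8)})


def random_distance_matrix(rng, n, labels=None):
    """Valid random DistanceMatrix (triangle inequality not required)."""
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    labels = labels or [f"A{i:02d}" for i in range(n)]
    return DistanceMatrix(labels, m)
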