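import numpy as np
import pandas as pd
import pytest

import astrodirac as ad


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-noise cohort with networks, shared across read-only tests."""
    cfg = ad.SimConfig(
        n_genes=300,
        samples_per_phenotype={p: 8 for p in ad.PHENOTYPES},
        n_networks=12,
        network_size_range=(5, 12),
        seed=11,
    )
    nets = ad.generate_networks(cfg)
    matrix, labels, probes, truth = ad.generate_cohort(cfg, nets)
    return cfg, nets, matrix, labels, probes, truth


def toy_matrix(values, layer="intensity", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ad.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), layer=layer)


def toy_labels(mapping, universe=ad.PHENOTYPES):
    return ad.PhenotypeLabels(pd.Series(mapping), universe=universe)
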