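import numpy as np
import pandas as pd
import pytest

import httimpute as h


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-pathway compendium shared across tests."""
    cfg = h.SimConfig(
        n_probes=120,
        n_pathways=6,
        probes_per_pathway=15,
        n_chemicals=10,
        seed=7,
    )
    matrix, ontology, truth = h.simulate_compendium(cfg)
    return matrix, ontology, truth, cfg


def make_matrix(values, probes=None, samples=None, meta=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"P{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j:03d}" for j in range(values.shape[1])]
    return h.ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples), meta)


def make_categorized(codes, probes=None, samples=None, meta=None):
    codes = np.asarray(codes, dtype=np.int8)
    probes = probes or [f"P{i:03d}" for i in range(codes.shape[0])]
    samples = samples or [f"S{j:03d}" for j in range(codes.shape[1])]
    return h.CategorizedMatrix(pd.DataFrame(codes, index=probes, columns=samples), meta)
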