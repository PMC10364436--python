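import numpy as np
import pandas as pd
import pytest

from cernet import SimParams, simulate_counts, simulate_targets
from cernet.io import CountMatrix


def small_params(seed: int = 0, **overrides) -> SimParams:
    """Scaled-down generator settings for fast unit tests."""
    defaults = dict(
        n_mrna=120, n_lnc=40, n_circ=12, n_mirna=24,
        n_modules=2, module_size=30,
        n_cis_pairs=5, n_lnc_triads=6, n_circ_triads=3, n_triad_mirnas=5,
        n_isolated_de={"mRNA": 10, "lncRNA": 5, "circRNA": 3, "miRNA": 5},
        seed=seed,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    params = small_params(seed=7)
    cm, samples, truth, ann = simulate_counts(params)
    targets = simulate_targets(truth, params)
    return {"params": params, "cm": cm, "samples": samples, "truth": truth,
            "ann": ann, "targets": targets}


def toy_count_matrix(values, feature_ids=None, sample_ids=None, rna_class="mRNA",
                     lengths=None) -> CountMatrix:
    values = np.asarray(values)
    n, m = values.shape
    feature_ids = feature_ids or [f"g{i}" for i in range(n)]
    sample_ids = sample_ids or [f"s{j}" for j in range(m)]
    counts = pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                          columns=sample_ids)
    classes = pd.Series(rna_class, index=counts.index) if isinstance(rna_class, str) \
        else pd.Series(rna_class, index=counts.index)
    lengths = pd.Series(lengths if lengths is not None else 1000, index=counts.index)
    return CountMatrix(counts, classes, lengths)
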