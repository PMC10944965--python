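import numpy as np
import pandas as pd
import pytest

from methclock.io_formats import MethylationStudy


def make_study(
    n_probes: int = 6,
    n_samples: int = 6,
    n_gse: int = 2,
    seed: int = 0,
    ages=None,
) -> MethylationStudy:
    """Small handcrafted beta study: valid, no missing values."""
    rng = np.random.default_rng(seed)
    cpgs = [f"cg{i:05d}" for i in range(n_probes)]
    sids = [f"S{i:03d}" for i in range(n_samples)]
    beta = pd.DataFrame(rng.uniform(0.05, 0.95, size=(n_probes, n_samples)),
                        index=pd.Index(cpgs, name="cpg_id"), columns=sids)
    if ages is None:
        ages = rng.uniform(25, 80, size=n_samples)
    samples = pd.DataFrame({
        "sample_id": sids,
        "gse_id": [f"GSE{i % n_gse}" for i in range(n_samples)],
        "age": np.asarray(ages, dtype=float),
        "sex": ["F" if i % 2 else "M" for i in range(n_samples)],
        "tissue_code": "A12.207.152",
        "status": "control",
        "family_id": sids,
    })
    probes = pd.DataFrame({
        "cpg_id": cpgs,
        "chromosome": [str(1 + i % 22) for i in range(n_probes)],
        "gene_symbols": [f"GENE{i}" for i in range(n_probes)],
        "probe_class": "cg",
        "unreliable": False,
    })
    return MethylationStudy(beta, samples, probes)


@pytest.fixture
def small_study():
    return make_study()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
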