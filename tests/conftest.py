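import numpy as np
import pandas as pd
import pytest

from swineclock import MethylationDataset


def make_dataset(betas: np.ndarray, ages, species="pig", tissue="blood",
                 breed="domestic", sex=None, island=None, mappable=None,
                 probe_ids=None, sample_ids=None) -> MethylationDataset:
    """Hand-built dataset from a probes x samples array and metadata vectors."""
    p, n = betas.shape
    probe_ids = probe_ids or [f"cg{i:04d}" for i in range(p)]
    sample_ids = sample_ids or [f"s{j:03d}" for j in range(n)]

    def vec(v, size, default):
        if v is None:
            v = default
        if np.isscalar(v) or isinstance(v, str):
            return [v] * size
        return list(v)

    samples = pd.DataFrame(
        {
            "species": vec(species, n, "pig"),
            "breed": vec(breed, n, "domestic"),
            "tissue": vec(tissue, n, "blood"),
            "sex": vec(sex, n, "F"),
            "age_years": list(ages),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    probes = pd.DataFrame(
        {
            "chrom": ["chr1"] * p,
            "pos": np.arange(1, p + 1) * 1000,
            "nearest_gene": [f"G{i}" for i in range(p)],
            "dist_to_tss": np.linspace(-5000, 5000, p).astype(int),
            "island": vec(island, p, False),
            "mappable": vec(mappable, p, True),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return MethylationDataset(
        pd.DataFrame(betas, index=probes.index, columns=samples.index), samples, probes
    )


@pytest.fixture
def toy_dataset():
    rng = np.random.default_rng(0)
    betas = rng.uniform(0.1, 0.9, (10, 8))
    ages = np.linspace(0.5, 6.0, 8)
    return make_dataset(betas, ages)
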