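import numpy as np
import pandas as pd
import pytest

import epiage as ea


@pytest.fixture(scope="session")
def small_cohort():
    """Compact two-dataset cohort for fast unit tests."""
    spec = ea.SyntheticSpec(n_sites=400, rng_seed=7)
    datasets, truth = ea.generate_bulk(spec)
    return datasets, truth


@pytest.fixture(scope="session")
def small_clock(small_cohort):
    datasets, _ = small_cohort
    model, report = ea.train_clock(datasets, n_sites=100)
    return model


@pytest.fixture(scope="session")
def reference_cohort():
    """The reference synthetic cohort (generator defaults), split 30/10
    training/held-out per dataset."""
    spec = ea.SyntheticSpec(rng_seed=11)
    datasets, truth = ea.generate_bulk(spec)
    train = [ds.subset_samples(ds.meta.index[:30]) for ds in datasets]
    test = [ds.subset_samples(ds.meta.index[30:]) for ds in datasets]
    return train, test, truth


@pytest.fixture(scope="session")
def reference_clock(reference_cohort):
    train, _, _ = reference_cohort
    model, _ = ea.train_clock(train, n_sites=750)
    return model


def make_bulk(meth, total, ages, dataset_id="D1", sites=None, tissue="blood"):
    """Small BulkDataset from plain arrays (samples x sites)."""
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    n_samp, n_site = meth.shape
    if sites is None:
        sites = [("chr1", 100 + 10 * j) for j in range(n_site)]
    idx = pd.Index([f"{dataset_id}_s{i}" for i in range(n_samp)], name="sample_id")
    meta = pd.DataFrame({"age_weeks": ages, "dataset_id": dataset_id,
                         "tissue": tissue, "cell_type": pd.NA}, index=idx)
    cols = ea.site_index(sites)
    return ea.BulkDataset(
        meta=meta,
        meth=pd.DataFrame(meth, index=idx, columns=cols),
        total=pd.DataFrame(total, index=idx, columns=cols),
    )
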