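import pandas as pd
import pytest

import biomebridge as bb


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset shared across tests (seed 1)."""
    return bb.simulate_dataset(bb.SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def pooled(dataset):
    return {dom: bb.pool_replicates(t, dataset.metadata)
            for dom, t in dataset.tables.items()}


def make_table(values, otus=None, samples=None, domain="bacteria"):
    """Small OtuTable from a nested list of counts."""
    otus = otus or [f"OTU{i + 1}" for i in range(len(values))]
    samples = samples or [f"S{j + 1}" for j in range(len(values[0]))]
    return bb.OtuTable(
        counts=pd.DataFrame(values, index=otus, columns=samples),
        domain_label=domain)
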