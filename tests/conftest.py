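import numpy as np
import pandas as pd
import pytest

from fmtomics.prep import CountTable, SampleMeta
from fmtomics.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast end-to-end tests."""
    return SimConfig(
        n_patients=30,
        n_genera=30,
        n_metabolites=80,
        n_anchor_samples=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size trial-like dataset (74 patients)."""
    return simulate_all(SimConfig(seed=202))


@pytest.fixture()
def toy_counts():
    counts = pd.DataFrame(
        [[10, 5, 0, 1], [0, 8, 4, 2], [3, 3, 3, 3]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "b1", "c1"],
    )
    taxonomy = pd.DataFrame(
        {
            "family": ["Aface", "Aface", "Bface", "Cface"],
            "genus": ["GenA", "GenA", "GenB", None],
        },
        index=["a1", "a2", "b1", "c1"],
    )
    return CountTable(counts, taxonomy)


@pytest.fixture()
def toy_meta():
    tbl = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p1", "p2", "p2", "d1"],
            "role": ["patient"] * 5 + ["donor"],
            "arm": ["FMT"] * 3 + ["placebo"] * 2 + [pd.NA],
            "timepoint": ["pre", "post10", "post28", "pre", "post10", "donor"],
            "donor_id": ["d1"] * 3 + [pd.NA] * 2 + [pd.NA],
            "outcome": [0, 0, 0, 1, 1, pd.NA],
            "prophylaxis": ["PTCy"] * 5 + [pd.NA],
        },
        index=pd.Index(["p1_pre", "p1_p10", "p1_p28", "p2_pre", "p2_p10", "d1_s"], name="sample_id"),
    )
    return SampleMeta(tbl)
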