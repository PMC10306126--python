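import numpy as np
import pandas as pd
import pytest

import fosnet as fn


@pytest.fixture
def toy_counts() -> fn.FosCountTable:
    """3 regions x 4 subjects, two per group."""
    counts = pd.DataFrame(
        {
            "s1": [10, 20, 30],
            "s2": [12, 22, 33],
            "s3": [50, 60, 70],
            "s4": [55, 66, 77],
        },
        index=["A", "B", "C"],
    )
    groups = {"s1": fn.CONTROL, "s2": fn.CONTROL, "s3": fn.TREATMENT, "s4": fn.TREATMENT}
    return fn.FosCountTable(counts=counts, group_of_subject=groups)


@pytest.fixture
def cholinergic_metadata() -> fn.RegionMetadata:
    """The seven long-range cholinergic regions plus a few plain regions."""
    chol = fn.default_cholinergic_metadata().reset_index()
    extra = pd.DataFrame(
        {
            "region_id": ["ACA", "CP", "VTA", "CUN"],
            "name": ["anterior cingulate", "caudoputamen", "ventral tegmental", "cuneiform"],
            "anatomic_group": ["cortical plate", "striatum", "midbrain", "midbrain"],
            "cholinergic_group": [None] * 4,
            "subsystem": [None] * 4,
        }
    )
    df = pd.concat([chol, extra], ignore_index=True).set_index("region_id")
    return fn.RegionMetadata(table=df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
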