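import numpy as np
import pandas as pd
import pytest

from anonlattice import (AttributeDefinition, AttributeSpec, Dataset,
                         GeneralizationHierarchy, Role, SyntheticSpec,
                         generate_dataset, toy8)


@pytest.fixture
def toy():
    return toy8()


@pytest.fixture
def outlier_dataset():
    """20 records over one QI: 4x4 common values plus 4 singleton outliers.

    Under k=4, global recoding at level 0 must suppress the four outliers
    (quality 80%); local recoding rescues them at level 1 in a second
    iteration (quality ~91.4%).
    """
    rows = [(f"a{i}",) for i in range(1, 5) for _ in range(4)]
    rows += [(f"b{i}",) for i in range(1, 5)]
    table = tuple(
        (f"a{i}", "A", "*") for i in range(1, 5)
    ) + tuple((f"b{i}", "B", "*") for i in range(1, 5))
    hier = GeneralizationHierarchy("v", table)
    frame = pd.DataFrame(rows, columns=["v"], dtype=object)
    return Dataset((AttributeDefinition("v", Role.QUASI_IDENTIFYING, hier),),
                   frame)


def random_instance(rng: np.random.Generator, max_attrs: int = 5,
                    max_records: int = 200):
    """Small random dataset + hierarchies (heights <= 3) for oracle tests."""
    m = int(rng.integers(1, max_attrs + 1))
    attrs = tuple(
        AttributeSpec(domain_size=int(rng.integers(2, 9)), branching_factor=2,
                      distribution="zipf" if rng.random() < 0.5 else "uniform")
        for _ in range(m))
    spec = SyntheticSpec(n_records=int(rng.integers(20, max_records + 1)),
                         attributes=attrs, seed=int(rng.integers(0, 2**31)))
    ds, _ = generate_dataset(spec)
    return ds
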