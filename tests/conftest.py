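import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import binprofiler as bp
from binprofiler.io_model import MOA, PLATE, TREATMENT, WELL

settings.register_profile("default", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("default")


SMALL_CONFIG = bp.SyntheticConfig(
    seed=1,
    plates=2,
    dmso_wells_per_plate=6,
    cells_per_well=120,
    n_parameters=20,
    n_noisy=4,
    n_degenerate=1,
    moa_classes=3,
    compounds_per_class=2,
    signature_size=2,
)


@pytest.fixture(scope="session")
def small_screen():
    """A fast two-plate screen with planted noisy/degenerate/informative parameters."""
    return bp.generate_screen(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_binned(small_screen):
    table, _ = small_screen
    binned, edges = bp.bin_profiles(table)
    return binned, edges


@pytest.fixture(scope="session")
def default_screen():
    """The default study conditions: 2 plates, 20 DMSO wells/plate, ~500
    cells/well, 100 parameters with 20 noisy (drift sd 0.5) and 2 degenerate."""
    return bp.generate_screen(bp.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_binned(default_screen):
    table, _ = default_screen
    binned, edges = bp.bin_profiles(table)
    return binned, edges


@pytest.fixture()
def tiny_table():
    """Six cells, two wells, two features, on one plate with DMSO controls."""
    df = pd.DataFrame(
        {
            PLATE: ["P1"] * 6,
            WELL: ["w1", "w1", "w1", "w2", "w2", "w2"],
            TREATMENT: ["DMSO"] * 3 + ["cpdA"] * 3,
            MOA: [None] * 3 + ["moaA"] * 3,
            "f1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "f2": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0],
        }
    )
    return bp.CellFeatureTable(data=df, features=("f1", "f2"))


def make_matrix(vectors, labels, treatments=None, ids=None, mode="well_average"):
    """Build a FingerprintMatrix from raw vectors for classifier tests."""
    vectors = np.asarray(vectors, dtype=float)
    n, p = vectors.shape
    data = pd.DataFrame(vectors, columns=[f"f{j}" for j in range(p)])
    data.insert(0, "profile_id", ids if ids is not None else [f"id{i:03d}" for i in range(n)])
    data.insert(1, TREATMENT, treatments if treatments is not None else [f"t{i}" for i in range(n)])
    data.insert(2, MOA, list(labels))
    return bp.FingerprintMatrix(
        data=data, features=tuple(f"f{j}" for j in range(p)), mode=mode
    )
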