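import numpy as np
import pandas as pd
import pytest

from mmdscreen import ScreenDataset, SimConfig, scale_unit_variance, simulate_screen


def make_records(rows):
    """Rows of (structure_id, set_id, population_id, is_control, oncogene,
    area, circularity) -> records frame."""
    return pd.DataFrame(
        rows,
        columns=[
            "structure_id",
            "set_id",
            "population_id",
            "is_control",
            "oncogene",
            "area",
            "circularity",
        ],
    )


@pytest.fixture
def toy_dataset():
    """Two populations (control + one knockdown) in one set, 6 structures."""
    rows = [
        ("s1", "setA", "control", True, "none", 100.0, 0.9),
        ("s2", "setA", "control", True, "none", 120.0, 0.85),
        ("s3", "setA", "control", True, "none", 110.0, 0.95),
        ("s4", "setA", "shX", False, "none", 40.0, 0.5),
        ("s5", "setA", "shX", False, "none", 50.0, 0.55),
        ("s6", "setA", "shX", False, "none", 45.0, 0.6),
    ]
    return ScreenDataset(records=make_records(rows))


@pytest.fixture(scope="session")
def null_screen():
    """Small all-null synthetic screen (3 sets, ~40 structures/population)."""
    cfg = SimConfig(n_sets=3, structures_per_population=40, seed=20240917)
    ds, truth = simulate_screen(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def null_features(null_screen):
    ds, _ = null_screen
    return scale_unit_variance(ds, "none")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
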