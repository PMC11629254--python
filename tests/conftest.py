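import numpy as np
import pandas as pd
import pytest

from lipidauth import screening, synthetic_data
from lipidauth.preprocess import FeatureTable

#: Seed for every seeded fixture in the suite; fixed once.
SUITE_SEED = 1


def make_table(values, regions, parts, lipid_ids=None, roles=None) -> FeatureTable:
    """Assemble a small FeatureTable from raw pieces."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if lipid_ids is None:
        lipid_ids = [f"L{j + 1}" for j in range(p)]
    idx = pd.Index([f"S{i + 1}" for i in range(n)], name="sample_id")
    meta = {"region": regions, "part": parts}
    if roles is not None:
        meta["role"] = roles
    return FeatureTable(
        pd.DataFrame(values, index=idx, columns=lipid_ids),
        pd.DataFrame(meta, index=idx),
    )


def two_group_table(rng, n_nx=6, n_non=12, n_lipids=5, shift=None, part="LT"):
    """NX vs non-NX single-part table with optional per-lipid mean shifts."""
    shift = np.zeros(n_lipids) if shift is None else np.asarray(shift, dtype=float)
    base = rng.normal(10.0, 1.0, (n_nx + n_non, n_lipids))
    base[:n_nx] += shift
    regions = ["NX"] * n_nx + ["GS"] * (n_non // 2) + ["IM"] * (n_non - n_non // 2)
    return make_table(np.abs(base) + 1.0, regions, [part] * (n_nx + n_non))


@pytest.fixture(scope="session")
def default_spec():
    return synthetic_data.default_spec(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def default_table(default_spec):
    return synthetic_data.generate(default_spec, seed=SUITE_SEED)


@pytest.fixture(scope="session")
def screen_lt(default_table):
    return screening.screen_part(default_table, "LT")


@pytest.fixture(scope="session")
def screen_km(default_table):
    return screening.screen_part(default_table, "KM")


@pytest.fixture(scope="session")
def marker_panel(screen_lt, screen_km):
    return screening.intersect_panel(screen_lt, screen_km)
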