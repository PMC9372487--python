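import numpy as np
import pandas as pd
import pytest

from isowue.isotopes import derive_traits
from isowue.simulate import TransectConfig, generate_transect


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic transect plus its derived-traits table."""
    cfg = TransectConfig(
        n_sites=8,
        aridity_range=(0.45, 0.80),
        richness_at_low_aridity=20,
        richness_slope=-15.0,
        seed=11,
    )
    ds = generate_transect(cfg)
    derived = derive_traits(ds.leaf_samples, ds.sites)
    return ds, derived


@pytest.fixture(scope="session")
def c3_derived(small_dataset):
    _, derived = small_dataset
    return derived[derived["pathway"] == "C3"].reset_index(drop=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def balanced_records():
    """Balanced 5 species x 5 sites x 3 reps table with known effects."""
    rng = np.random.default_rng(7)
    sp_eff = {f"sp{i}": e for i, e in enumerate([0.0, 2.0, -1.0, 4.0, -3.0])}
    si_eff = {f"S{j}": e for j, e in enumerate([0.0, 1.5, -0.5, 2.5, -2.0])}
    rows = []
    for sp, a in sp_eff.items():
        for si, b in si_eff.items():
            inter = rng.normal(0, 1.0)
            for _ in range(3):
                rows.append((sp, si, 50.0 + a + b + inter + rng.normal(0, 0.8)))
    return pd.DataFrame(rows, columns=["species_id", "site_id", "iWUE"])
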