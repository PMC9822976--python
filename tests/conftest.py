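import numpy as np
import pandas as pd
import pytest

from acertail import CancerPanelSpec, MergedVector, gen_cancer_like_panel  # noqa: F401


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_merged():
    """Six pooled maxima from one component with unit limits."""
    v = [0.5, 0.9, 0.4, 0.95, 0.2, 0.97]
    return MergedVector(
        values=v,
        times=np.arange(6.0),
        source=np.array(["X"] * 6, dtype=object),
        limits=np.ones(6),
        span_t=6.0,
        n_components=1,
    )


@pytest.fixture
def cancer_panel():
    return gen_cancer_like_panel(CancerPanelSpec(seed=7))


@pytest.fixture
def owid_csv(tmp_path):
    """A small long-format file in the Entity/Code/Year dialect."""
    rows = []
    for entity, code in [("Aland", "ALA"), ("Borduria", "BOR")]:
        for year in (2000, 2001, 2002):
            deaths = {"Aland": 120, "Borduria": 250}[entity] + year - 2000
            pop = {"Aland": 50_000, "Borduria": 80_000}[entity]
            rows.append((entity, code, year, deaths, pop))
    frame = pd.DataFrame(rows, columns=["Entity", "Code", "Year", "Deaths", "Population"])
    path = tmp_path / "owid.csv"
    frame.to_csv(path, index=False)
    return path
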