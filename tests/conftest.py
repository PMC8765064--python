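import numpy as np
import pandas as pd
import pytest

from cryograd import AsvTable, PipelineConfig, TaxonomyMap


@pytest.fixture
def counts_table() -> AsvTable:
    data = pd.DataFrame(
        [[12, 0, 3, 40], [5, 7, 0, 22], [0, 9, 1, 18]],
        index=["S1", "S2", "S3"],
        columns=["a1", "a2", "a3", "a4"],
    )
    return AsvTable(data, kind="counts")


@pytest.fixture
def taxonomy_all_bacteria() -> TaxonomyMap:
    ranks = ["domain", "phylum", "class", "order", "family", "genus"]
    rows = {
        asv: ["Bacteria", "Actinobacteria", "c", "o", "f", np.nan]
        for asv in ["a1", "a2", "a3", "a4"]
    }
    return TaxonomyMap(pd.DataFrame.from_dict(rows, orient="index", columns=ranks))


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


def make_meta(elevations, seed=0, feature="F1"):
    """Metadata frame with all ten analysis variables filled in."""
    rng = np.random.default_rng(seed)
    n = len(elevations)
    meta = pd.DataFrame({"elevation": np.asarray(elevations, dtype=float)},
                        index=[f"S{i + 1}" for i in range(n)])
    for var in ("nitrate", "chloride", "total_cations", "total_anions",
                "total_salt", "perchlorate", "chlorate", "nh3", "sio2"):
        meta[var] = rng.uniform(1.0, 100.0, size=n)
    meta["feature"] = feature
    return meta
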