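import numpy as np
import pandas as pd
import pytest

from ziclust import default_config, generate_dscs


@pytest.fixture(scope="session")
def sex_only_poisson_data():
    """Reduced survey: sex as the only covariate, Poisson counts."""
    cfg = default_config(
        covariates=("sex",), family="poisson", dispersion=None, seed=101
    )
    return cfg, generate_dscs(cfg)


@pytest.fixture(scope="session")
def sex_only_cmp_data():
    """Reduced survey with the default over-dispersed CMP truth."""
    cfg = default_config(covariates=("sex",), seed=11)
    return cfg, generate_dscs(cfg)


@pytest.fixture(scope="session")
def tiny_cluster_frame():
    """Hand-built 3-cluster frame for oracle comparisons."""
    rng = np.random.default_rng(7)
    rows = []
    for city, n in (("A", 4), ("B", 3), ("C", 5)):
        for _ in range(n):
            rows.append(
                {
                    "city_id": city,
                    "y": int(rng.poisson(1.2)),
                    "sex": rng.choice(["Female", "Male"]),
                }
            )
    return pd.DataFrame(rows)
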