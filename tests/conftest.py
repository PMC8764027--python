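import numpy as np
import pandas as pd
import pytest

from muevolab.config import RunConfig
from muevolab.simulate import SimParams


@pytest.fixture(scope="session")
def params() -> SimParams:
    return SimParams.default()


@pytest.fixture(scope="session")
def ecology_params(params) -> SimParams:
    """Mutation-free copy of the defaults for integration/ecology checks."""
    from dataclasses import replace
    return replace(params, mu_res=0.0, mu_rev=0.0)


@pytest.fixture()
def small_cfg() -> RunConfig:
    return RunConfig(n_lineages=2, n_technical=2)


def make_transfer_table(od_by_lineage: dict[str, list[float]],
                        culture_type: str = "CO",
                        antibiotic: str = "NONE") -> pd.DataFrame:
    """Build a minimal valid transfers table from per-lineage OD series."""
    rows = []
    for lid, ods in od_by_lineage.items():
        dead = False
        for t, od in enumerate(ods):
            alive = od >= 0.01 and not dead
            rows.append({"lineage_id": lid, "culture_type": culture_type,
                         "antibiotic": antibiotic, "transfer": t,
                         "od600": od, "concentration": 0.0, "alive": alive})
            if not alive:
                dead = True
                break
    return pd.DataFrame(rows)


@pytest.fixture()
def transfer_table() -> pd.DataFrame:
    return make_transfer_table({
        "L0": [0.5, 0.6, 0.55, 0.6],
        "L1": [0.5, 0.4, 0.005],
        "L2": [0.3, 0.35, 0.4, 0.45],
    })
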