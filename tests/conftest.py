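import numpy as np
import pandas as pd
import pytest

from spikemads import SimConfig, simulate_dataset
from spikemads.stages import DEFAULT_GRID


@pytest.fixture(scope="session")
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """Ground truth + Cq table for the canonical seed-42 run."""
    return simulate_dataset(default_config, 42)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


def make_cq(records):
    """Build a long-format Cq table from (gene, ctype, cond, rep, cq) tuples."""
    return pd.DataFrame.from_records(
        records,
        columns=["gene", "condition_type", "condition", "replicate", "cq"],
    )


@pytest.fixture
def flat_cq():
    """Two targets and two references, all at Cq 20, over 3 stage conditions."""
    rows = []
    for gene in ("t1", "t2", "refA", "refB"):
        for cond in ("W1", "W2", "W3"):
            for rep in (1, 2, 3):
                rows.append((gene, "stage", cond, rep, 20.0))
    return make_cq(rows)
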