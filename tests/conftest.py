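import numpy as np
import pandas as pd
import pytest

from gutcohort import AbundanceTable, GeneCatalog, Metadata
from gutcohort import synthetic


@pytest.fixture
def small_table() -> AbundanceTable:
    """3 samples x 4 genera, percent scale."""
    df = pd.DataFrame(
        {
            "Bacteroides": [60.0, 40.0, 10.0],
            "Prevotella": [5.0, 6.0, 30.0],
            "Faecalibacterium": [20.0, 30.0, 40.0],
            "Alistipes": [15.0, 24.0, 20.0],
        },
        index=["s1", "s2", "s3"],
    )
    return AbundanceTable(df, rank="genus")


@pytest.fixture
def small_meta() -> Metadata:
    return Metadata(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "participant_id": ["p1", "p2", "p3"],
                "region": ["Beijing", "Beijing", "Wuxi"],
                "location": ["Beijing-L1", "Beijing-L2", "Wuxi-L1"],
            }
        )
    )


@pytest.fixture
def catalog() -> GeneCatalog:
    return GeneCatalog(
        {"tetA_1_SYN00001": 100, "blaCTX_1_SYN00002": 200, "aph3_1_SYN00003": 450},
        {"tetA_1_SYN00001": "tetracycline"},
    )


@pytest.fixture(scope="session")
def longitudinal():
    """Shared 7-participant x 12-month cohort (abundance, metadata)."""
    return synthetic.simulate_cohort(synthetic.default_longitudinal(seed=11))
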