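import numpy as np
import pandas as pd
import pytest

from crosscoloc import LDReference, SumStatsTable
from crosscoloc.sumstats import COLUMNS


def make_table(trait="t", **cols) -> SumStatsTable:
    """Build a SumStatsTable from column overrides; scalars broadcast."""
    ids = cols.pop("variant_id")
    n = len(ids)
    defaults = {
        "chrom": "1",
        "pos": list(range(1, n + 1)),
        "effect_allele": "A",
        "other_allele": "G",
        "beta": 0.1,
        "se": 0.1,
        "pvalue": 0.5,
        "maf": 0.25,
        "info": 0.99,
    }
    defaults.update(cols)
    data = {"variant_id": list(ids)}
    for name in COLUMNS[1:]:
        v = defaults[name]
        data[name] = [v] * n if np.ndim(v) == 0 else list(v)
    return SumStatsTable(trait, pd.DataFrame(data))


def make_reference(table: SumStatsTable, genotypes: np.ndarray) -> LDReference:
    """LD reference whose columns follow the table's variant order."""
    return LDReference(
        table.df["variant_id"].tolist(), table.df["pos"].to_numpy(), genotypes
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
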