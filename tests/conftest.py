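import numpy as np
import pandas as pd
import pytest

from ndnet.data_io import CohortTable
from ndnet.schema import AGE_COLUMNS, SEX_COLUMN, cohort_schema
from ndnet.synthetic import CohortSimConfig, default_planted_network, simulate_cohort


@pytest.fixture(scope="session")
def schema_a():
    return cohort_schema("cohort_A")


@pytest.fixture(scope="session")
def schema_b():
    return cohort_schema("cohort_B")


@pytest.fixture(scope="session")
def paper_like_net(schema_a):
    return default_planted_network("paper_like", schema_a)


@pytest.fixture(scope="session")
def complete_cohort(paper_like_net, schema_a):
    """n = 5,000 complete (no missingness) synthetic cohort."""
    cfg = CohortSimConfig(n_individuals=5000, seed=11, missing_rate=0.0)
    return simulate_cohort(paper_like_net, schema_a, cfg)


@pytest.fixture(scope="session")
def big_complete_cohort(paper_like_net, schema_a):
    """n = 20,000 complete cohort for rank-correlation oracles."""
    cfg = CohortSimConfig(n_individuals=20000, seed=12, missing_rate=0.0)
    return simulate_cohort(paper_like_net, schema_a, cfg)


@pytest.fixture(scope="session")
def missing_cohort(paper_like_net, schema_a):
    cfg = CohortSimConfig(
        n_individuals=5000, seed=13, missing_rate=0.15, all_trait_missing_frac=0.02
    )
    return simulate_cohort(paper_like_net, schema_a, cfg)


def make_table(values: pd.DataFrame, schema, family=None) -> CohortTable:
    """Tiny-table helper: fills covariates with constants plus jitter-free ages."""
    n = len(values)
    cov = pd.DataFrame({c: np.full(n, 9.0) for c in AGE_COLUMNS})
    cov[SEX_COLUMN] = np.arange(n) % 2
    cov = cov[list(AGE_COLUMNS) + [SEX_COLUMN]]
    fam = pd.Series(family) if family is not None else None
    return CohortTable(
        values=values, covariates=cov, schema=schema, cohort_id=schema.cohort_id,
        family_id=fam,
    )


def blank_values(schema, n: int) -> pd.DataFrame:
    """All-observed table of mid-scale scores in canonical order."""
    data = {}
    for v in schema.variables:
        mid = (v.score_min + v.score_max) / 2
        data[v.name] = np.linspace(v.score_min + 0.1, mid, n)
    return pd.DataFrame(data, columns=list(schema.names))
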