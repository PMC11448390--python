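import numpy as np
import pandas as pd
import pytest

from microdyn import (
    AbundanceSeriesTable,
    AnalysisConfig,
    SyntheticSpec,
    rarefy_counts,
    simulate_subject,
)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def tiny_table():
    """3 days x 2 ASVs with a gap at day 2."""
    df = pd.DataFrame({"A": [5, 3, 7], "B": [1, 0, 2]}, index=[0, 1, 3])
    return AbundanceSeriesTable(df, subject_id="tiny")


@pytest.fixture(scope="session")
def synthetic_subject():
    """One full synthetic subject (200 days, 60 ASVs) with truth labels."""
    return simulate_subject(SyntheticSpec(rng_seed=7))


@pytest.fixture(scope="session")
def rarefied_subject(synthetic_subject):
    table, truth = synthetic_subject
    rarefied, report = rarefy_counts(table, depth=5000, seed=13)
    assert not report.dropped_days
    return rarefied, truth


def write_tsv(path, df):
    out = df.copy()
    out.index.name = "day"
    out.to_csv(path, sep="\t")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(42)
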