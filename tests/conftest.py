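import numpy as np
import pandas as pd
import pytest

from metabosig.containers import FeatureMatrix, SampleMetadata
from metabosig.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed 11)."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def plasma_prepared(default_cohort):
    """Plasma matrix of the default cohort, log2 + imputed + Pareto."""
    from metabosig import qc

    plasma, _, metadata, _, truth = default_cohort
    logged = qc.knn_impute(qc.log_transform(plasma))
    pareto = qc.pareto_scale(logged)
    plasma_meta = SampleMetadata(metadata.table.loc[plasma.sample_ids])
    return logged, pareto, plasma_meta, truth


@pytest.fixture
def tiny_matrix():
    vals = pd.DataFrame(
        [[8.0, 1.0, 4.0], [2.0, 2.0, 4.0], [4.0, 4.0, 4.0]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3"],
    )
    return FeatureMatrix(vals, scale_state="raw")


def two_group_metadata(n_control: int, n_case: int, seed: int = 0) -> SampleMetadata:
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_control):
        rows.append((f"c{i}", "control", "M" if rng.random() < 0.5 else "F", float(rng.normal(35, 8))))
    for i in range(n_case):
        rows.append((f"d{i}", "case", "M" if rng.random() < 0.8 else "F", float(rng.normal(60, 8))))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "sex", "age"]).set_index("sample_id")
    return SampleMetadata(df)
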