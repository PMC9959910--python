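"""Shared fixtures: small simulated cohorts, generated at test time."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import lfqcohort as lc


@pytest.fixture(scope="session")
def desk_cohort():
    """One desk-scale cohort (600 proteins, 10+12 samples, 3 QC runs)."""
    return lc.simulate_cohort(lc.desk_config(seed=11))


@pytest.fixture(scope="session")
def clean_desk_cohort():
    """Desk cohort without contamination spikes or aberrant samples."""
    cfg = replace(lc.desk_config(seed=12), contamination_spikes=[], aberrant_samples=[])
    return lc.simulate_cohort(cfg)


@pytest.fixture()
def toy_matrix():
    """Tiny hand-checkable protein matrix."""
    df = pd.DataFrame(
        {
            "s1": [90.0, 1.0, 10.0],
            "s2": [100.0, 1000.0, 0.0],
            "s3": [110.0, 1.0, 10.0],
        },
        index=["A", "B", "C"],
    )
    return lc.IntensityMatrix(df)


@pytest.fixture()
def two_group_metadata():
    def make(n1, n2, n_qc=0):
        ids = (
            [f"M1_{i:02d}" for i in range(1, n1 + 1)]
            + [f"M2_{i:02d}" for i in range(1, n2 + 1)]
            + [f"QC{i}" for i in range(1, n_qc + 1)]
        )
        table = pd.DataFrame(
            {
                "group": ["MGS1"] * n1 + ["MGS2"] * n2 + ["QC"] * n_qc,
                "run_order": np.arange(1, len(ids) + 1),
            },
            index=pd.Index(ids, name="sample_id"),
        )
        return lc.SampleMetadata(table)

    return make
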