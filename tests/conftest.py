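import numpy as np
import pandas as pd
import pytest

from lupuscmap.core_io import ClinicalTable, ExpressionMatrix, RankedProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_expression():
    """3 genes x 3 samples (2 cases, 1 control)."""
    values = pd.DataFrame(
        {
            "case1": [5.0, 2.0, 7.0],
            "case2": [4.0, 3.0, 6.0],
            "ctrl1": [3.0, 2.5, 6.5],
        },
        index=["g1", "g2", "g3"],
    )
    roles = {"case1": "case", "case2": "case", "ctrl1": "control"}
    return ExpressionMatrix(values=values, sample_role=roles)


@pytest.fixture
def small_clinical():
    """2 patients x 3 visits, deliberately unsorted rows."""
    rows = [
        ("p2", 2, 6, 60.0, 25.0, 0, "c1"),
        ("p1", 1, 4, 50.0, 30.0, 1, "c1"),
        ("p1", 3, 10, 70.0, 15.0, 1, "c1"),
        ("p2", 1, 3, 55.0, 28.0, 0, "c1"),
        ("p1", 2, 8, 65.0, 20.0, 1, "c1"),
        ("p2", 3, 9, 68.0, 18.0, 0, "c1"),
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id", "visit_index", "sledai", "neut_pct", "lymph_pct",
            "nephritis", "cohort_id",
        ],
    )
    return ClinicalTable(df)


def make_profile(genes, stats=None):
    """RankedProfile from an already ordered gene list."""
    if stats is None:
        stats = np.linspace(1.0, -1.0, len(genes))
    return RankedProfile(genes=list(genes), stats=np.asarray(stats, dtype=float))


@pytest.fixture
def profile_factory():
    return make_profile
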