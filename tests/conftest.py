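import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from seqmate import ExpressionMatrix, MatingTable

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def worked_table() -> MatingTable:
    """25/25 availability per type and sex, 8/2/2/8 observed pairs."""
    return MatingTable(["A", "S"], [25, 25], [25, 25], [[8, 2], [2, 8]])


def make_matrix(values: dict, tissues=None, regimes=None, state="subsampled"):
    """Small ExpressionMatrix from {transcript: [per-sample values]}."""
    df = pd.DataFrame(values).T
    n = df.shape[1]
    if regimes is None:
        regimes = ["A"] * (n // 2) + ["S"] * (n - n // 2)
    if tissues is None:
        tissues = ["HT"] * n
    reps = []
    seen = {}
    for t, r in zip(tissues, regimes):
        seen[(t, r)] = seen.get((t, r), 0) + 1
        reps.append(seen[(t, r)])
    sample_ids = [f"{t}_{r}_{k}" for t, r, k in zip(tissues, regimes, reps)]
    df.columns = sample_ids
    meta = pd.DataFrame(
        {"tissue": tissues, "regime": regimes, "replicate": reps}, index=sample_ids
    )
    return ExpressionMatrix(df.astype(float), meta, state=state)


@pytest.fixture
def de_design():
    """Single-tissue two-regime three-replicate design."""
    return [("HT", r, k) for r in ("A", "S") for k in (1, 2, 3)]


@pytest.fixture
def two_tissue_design():
    return [(t, r, k) for t in ("HT", "Ab") for r in ("A", "S") for k in (1, 2, 3)]
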