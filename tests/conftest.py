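import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ovodiff as od

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_matrix(values, design=None, scale="linear", modality="protein"):
    """Helper: ExpressionMatrix from a plain dict/frame of columns."""
    frame = pd.DataFrame(values)
    if design is None:
        design = od.make_design(n_replicates=2).iloc[: frame.shape[1]]
        frame.columns = design.index
    return od.ExpressionMatrix.from_values(frame, design, scale=scale, modality=modality)


@pytest.fixture(scope="session")
def full_design():
    return od.make_design(n_replicates=2)


@pytest.fixture(scope="session")
def default_proteome():
    """Default-condition synthetic proteome (seed 0), shared across tests."""
    return od.generate_proteome(od.SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_proteome_run(default_proteome):
    from ovodiff.pipeline import run_proteome_pipeline

    matrix, _ = default_proteome
    return run_proteome_pipeline(matrix, pairing="stage_replicate")


@pytest.fixture(scope="session")
def averaged_design():
    """One column per (stage, treatment), replicate-averaged layout."""
    rows = [
        (f"{s}_{t}", s, t, 1)
        for s in od.STAGES
        for t in od.TREATMENTS
    ]
    return od.validate_design(
        pd.DataFrame(rows, columns=["sample_id", "stage", "treatment", "replicate"])
    )
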