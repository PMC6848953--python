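"""Shared fixtures: synthetic samples are generated once per session."""

import pandas as pd
import pytest

from fticrms.formula_assignment import assign_sample
from fticrms.synthetic_data import SyntheticSpec, generate_sample


@pytest.fixture(scope="session")
def recovery_sample():
    """The 500-compound recovery experiment: sample, ground truth, and
    the assignment table computed on it (0.2 ppm jitter, no drift)."""
    spec = SyntheticSpec(seed=7, n_compounds=500, jitter_ppm=0.2, contaminant_fraction=0.05)
    peaks, truth = generate_sample(spec)
    table = assign_sample(peaks)
    return peaks, truth, table


@pytest.fixture(scope="session")
def recovery_merged(recovery_sample) -> pd.DataFrame:
    peaks, truth, table = recovery_sample
    merged = truth.merge(
        table, left_on="observed_mz", right_on="mz", suffixes=("_true", "_assigned")
    )
    assert len(merged) == len(truth)
    return merged
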