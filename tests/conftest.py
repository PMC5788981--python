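import numpy as np
import pytest

from hwnraman import (
    CohortSpec,
    InstrumentResponse,
    LabeledDataset,
    make_axis,
    preprocess_cohort,
    simulate_cohort,
)
from hwnraman.synthetic import instrument_response_curve


@pytest.fixture(scope="session")
def axis():
    return make_axis()


def build_dataset(spec: CohortSpec, seed: int, config=None) -> LabeledDataset:
    """Simulate a cohort, preprocess it, and wrap it as a labeled dataset."""
    records = simulate_cohort(spec, config=config, seed=seed)
    ax = records[0].acquisition.axis
    response = InstrumentResponse(ax, instrument_response_curve(ax))
    processed, _ = preprocess_cohort([r.acquisition for r in records], response)
    return LabeledDataset.from_processed(processed)


@pytest.fixture(scope="session")
def small_dataset():
    """A 50-spectrum three-class cohort at the default class contrast."""
    return build_dataset(
        CohortSpec(n_normal=20, n_infiltrated=10, n_dense=20, n_patients=5), seed=42
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
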