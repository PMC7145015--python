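import numpy as np
import pandas as pd
import pytest

from besc.data_model import ExpressionMatrix, validate_annotation
from besc.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def tiny_expr():
    """3 probes x 4 samples with easy hand-checkable numbers."""
    return ExpressionMatrix(
        probe_ids=np.array(["p1", "p2", "p3"], dtype=object),
        sample_ids=np.array(["s1", "s2", "s3", "s4"], dtype=object),
        values=np.array([
            [1.0, 3.0, 5.0, 7.0],
            [2.0, 2.0, 2.0, 2.0],
            [0.0, 4.0, 8.0, 12.0],
        ]),
    )


@pytest.fixture
def tiny_ann():
    return validate_annotation(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "sample_type": ["A", "A", "B", "B"],
        "collection": ["c1", "c2", "c1", "c2"],
    }))


@pytest.fixture(scope="session")
def small_synthetic():
    """A small but structured compendium shared across tests."""
    cfg = SyntheticConfig(
        m=400, n_types=6, n_collections=12, samples_per_collection=6,
        L=4, noise_sd=0.4, seed=20260927,
    )
    return generate_dataset(cfg)
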