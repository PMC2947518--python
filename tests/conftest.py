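"""Shared fixtures: small synthetic reference datasets and a trained predictor."""

import numpy as np
import pytest

from brainage import ExpressionMatrix, SampleInfo, synth_reference, train_predictor


@pytest.fixture(scope="session")
def reference_data():
    """Default synthetic reference dataset (120 samples, 500 genes, noise 0.3)."""
    return synth_reference(seed=1)


@pytest.fixture(scope="session")
def trained_model(reference_data):
    expr, samples, _ = reference_data
    return train_predictor(expr, samples)


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix.from_arrays(
        ["g1", "g2"], ["s1", "s2", "s3"],
        np.array([[1.5, 2.25, -0.5], [7.0, 6.5, 8.125]]),
    )


@pytest.fixture
def mixed_samples():
    """Ten samples with both sexes and spread ages."""
    rows = []
    for j in range(10):
        rows.append(
            SampleInfo(
                sample_id=f"s{j}",
                age=30.0 + 6 * j,
                sex="female" if j % 2 == 0 else "male",
                group="control",
            )
        )
    return rows
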