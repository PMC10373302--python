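import numpy as np
import pytest

from maxminus_dropout.data_model import (BOOLEAN, CONTINUOUS, ClinicalTable,
                                         FeatureSchema)


@pytest.fixture
def small_schema() -> FeatureSchema:
    return FeatureSchema(
        feature_names=("dry_mouth", "thirst", "numbness", "age"),
        feature_types=(BOOLEAN, BOOLEAN, BOOLEAN, CONTINUOUS),
        class_labels=("dampness_heat", "qi_yin_deficiency"),
        continuous_ranges={"age": (0.0, 120.0)},
    )


@pytest.fixture
def small_table(small_schema) -> ClinicalTable:
    values = np.array([
        [1.0, 0.0, 1.0, 63.0],
        [0.0, 1.0, np.nan, 47.0],
        [1.0, np.nan, np.nan, 58.0],
        [0.0, 0.0, 1.0, 71.0],
        [1.0, 1.0, 0.0, 39.0],
        [np.nan, 1.0, 1.0, 55.0],
    ])
    mask = np.isnan(values)
    labels = np.array(["dampness_heat", "qi_yin_deficiency", "dampness_heat",
                       "qi_yin_deficiency", "dampness_heat", "qi_yin_deficiency"],
                      dtype=object)
    return ClinicalTable(values, mask, labels, small_schema)


def random_probability_matrix(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Rows drawn uniformly from the probability simplex."""
    g = rng.gamma(1.0, 1.0, size=(n, k))
    return g / g.sum(axis=1, keepdims=True)
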