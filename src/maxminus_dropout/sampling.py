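"""Negative mini-batch construction.

The method's own operator is max-minus sampling: subtract each row from the
per-feature maximum of its mini-batch, ``x_ng = max(x_b) - x_b``.  On 0/1
symptom columns that contain both values this is a bit-flip, and on mixed
rows it manufactures clinically incoherent profiles (e.g. a course of
treatment close to the patient's age) that belong to no class — exactly the
"unlike any real sample" property a negative example should have.  The two
baseline strategies used for comparison (in-batch class-mismatched rows and
schema-range random generation) are provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import FeatureSchema

MAX_MINUS = "max_minus"
IN_BATCH = "in_batch"
RANDOM_GENERATION = "random_generation"
NEGATIVE_STRATEGIES = (MAX_MINUS, IN_BATCH, RANDOM_GENERATION)


@dataclass(frozen=True)
class MiniBatch:
    """A complete (imputed) feature batch with aligned labels."""

    x_b: np.ndarray
    y_b: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x_b, dtype=np.float64)
        y = np.asarray(self.y_b)
        object.__setattr__(self, "x_b", x)
        object.__setattr__(self, "y_b", y)
        if x.ndim != 2 or x.shape[0] < 1:
            raise ValueError("x_b must be a non-empty 2-D matrix")
        if np.isnan(x).any():
            raise ValueError("mini-batches must be imputed; found NaN values")
        if y.shape != (x.shape[0],):
            raise ValueError("y_b must have one label per row")


@dataclass(frozen=True)
class NegativeBatch:
    """Negative samples, row-aligned with (and shaped like) the source batch."""

    x_ng: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "x_ng", np.asarray(self.x_ng, dtype=np.float64))
        if self.x_ng.ndim != 2:
            raise ValueError("x_ng must be 2-D")


def max_minus_negatives(batch: MiniBatch) -> NegativeBatch:
    """``x_ng[i, j] = max_i x_b[i, j] - x_b[i, j]`` with the maximum taken
    over the current mini-batch only.  Deterministic; a batch of one yields
    all-zero negatives."""
    col_max = batch.x_b.max(axis=0, keepdims=True)
    return NegativeBatch(col_max - batch.x_b)


def in_batch_negatives(batch: MiniBatch, rng: np.random.Generator) -> NegativeBatch:
    """Replace each row by a batch row whose label differs from its anchor's."""
    y = batch.y_b
    if np.unique(y).size < 2:
        raise ValueError("in-batch negatives need at least two classes in the batch")
    n = y.shape[0]
    x_ng = np.empty_like(batch.x_b)
    for i in range(n):
        candidates = np.flatnonzero(y != y[i])
        x_ng[i] = batch.x_b[rng.choice(candidates)]
    return NegativeBatch(x_ng)


def random_generation_negatives(schema: FeatureSchema, batch_size: int,
                                rng: np.random.Generator,
                                dataset: Optional[np.ndarray] = None,
                                max_retries: int = 100) -> NegativeBatch:
    """Draw rows uniformly within the schema's ranges: Bernoulli(0.5) on
    boolean features, Uniform(min, max) on continuous ones.  Rows colliding
    with any ``dataset`` row are resampled up to ``max_retries`` times."""
    bool_cols = schema.boolean_columns()
    lo = np.zeros(schema.n_features)
    hi = np.ones(schema.n_features)
    for j, name in enumerate(schema.feature_names):
        if not bool_cols[j]:
            if name not in schema.continuous_ranges:
                raise ValueError(f"no range declared for continuous feature {name!r}")
            lo[j], hi[j] = schema.continuous_ranges[name]

    def draw(k: int) -> np.ndarray:
        x = lo + (hi - lo) * rng.random((k, schema.n_features))
        x[:, bool_cols] = (rng.random((k, int(bool_cols.sum()))) < 0.5).astype(float)
        return x

    x_ng = draw(batch_size)
    if dataset is not None:
        dataset = np.asarray(dataset, dtype=np.float64)
        for _ in range(max_retries):
            collides = np.array([(np.abs(dataset - row).max(axis=1) == 0).any()
                                 for row in x_ng])
            if not collides.any():
                break
            x_ng[collides] = draw(int(collides.sum()))
        else:
            raise RuntimeError("could not generate collision-free negatives "
                               f"within {max_retries} retries")
    return NegativeBatch(x_ng)
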