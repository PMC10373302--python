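"""Missing-data imputation for mixed boolean/continuous clinical tables.

Boolean symptom columns support four strategies — mode (the default in the
final training protocol), random draws from the observed empirical
distribution, a Beta(1,1)–Bernoulli posterior predictive ("Bayesian"), and
constant fill (NaN-replace).  Continuous columns are always mean-imputed.
Column statistics are computed on the table passed in, never on the fills,
and observed cells are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import ClinicalTable, ValidationError

MODE = "mode"
RANDOM = "random"
BAYESIAN = "bayesian"
NAN_REPLACE = "nan_replace"
BOOLEAN_STRATEGIES = (MODE, RANDOM, BAYESIAN, NAN_REPLACE)

_STOCHASTIC = (RANDOM, BAYESIAN)


class AllMissingColumnError(ValueError):
    """A column has no observed values to estimate fill statistics from."""


@dataclass(frozen=True)
class ImputationPolicy:
    """How to fill missing cells: boolean strategy + mean for continuous."""

    boolean_strategy: str = MODE
    fill_value: float = 0.0          # nan_replace only
    seed: Optional[int] = None       # random / bayesian only
    train_only_statistics: bool = False  # see impute_dataset

    def __post_init__(self):
        if self.boolean_strategy not in BOOLEAN_STRATEGIES:
            raise ValueError(
                f"unknown boolean strategy {self.boolean_strategy!r}; "
                f"expected one of {BOOLEAN_STRATEGIES}")
        if self.boolean_strategy in _STOCHASTIC and self.seed is None:
            raise ValueError(f"{self.boolean_strategy} imputation requires a seed")


def _observed(column: np.ndarray, mask: np.ndarray, name: str = "column") -> np.ndarray:
    column = np.asarray(column, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise AllMissingColumnError(f"{name} has no observed values")
    return column[~mask]


def mode_impute(column: np.ndarray, mask: np.ndarray, name: str = "column") -> np.ndarray:
    """Fill missing cells with the most frequent observed value.

    Ties break to the smaller value, deterministically.
    """
    obs = _observed(column, mask, name)
    values, counts = np.unique(obs, return_counts=True)  # values sorted ascending
    fill = values[np.argmax(counts)]
    out = np.asarray(column, dtype=np.float64).copy()
    out[np.asarray(mask, dtype=bool)] = fill
    return out


def mean_impute(column: np.ndarray, mask: np.ndarray, name: str = "column") -> np.ndarray:
    """Fill missing cells with the arithmetic mean of observed values."""
    obs = _observed(column, mask, name)
    out = np.asarray(column, dtype=np.float64).copy()
    out[np.asarray(mask, dtype=bool)] = obs.mean()
    return out


def random_impute(column: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                  name: str = "column") -> np.ndarray:
    """Fill each missing cell with an independent draw from the empirical
    distribution of observed values in the column."""
    obs = _observed(column, mask, name)
    mask = np.asarray(mask, dtype=bool)
    out = np.asarray(column, dtype=np.float64).copy()
    out[mask] = rng.choice(obs, size=int(mask.sum()), replace=True)
    return out


def bayes_impute(column: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
                 name: str = "column") -> np.ndarray:
    """Beta(1,1)–Bernoulli posterior-predictive fill for a boolean column.

    With s observed ones out of m observations the posterior predictive is
    P(1) = (s+1)/(m+2); each missing cell is an independent Bernoulli draw.
    """
    obs = _observed(column, mask, name)
    if not np.isin(obs, (0.0, 1.0)).all():
        raise ValidationError(f"{name} is not boolean; bayes_impute requires 0/1 values")
    mask = np.asarray(mask, dtype=bool)
    p1 = posterior_predictive_p1(obs)
    out = np.asarray(column, dtype=np.float64).copy()
    out[mask] = (rng.random(int(mask.sum())) < p1).astype(np.float64)
    return out


def posterior_predictive_p1(observed: np.ndarray, a: float = 1.0, b: float = 1.0) -> float:
    """Closed-form Beta(a,b)–Bernoulli posterior predictive P(next = 1)."""
    observed = np.asarray(observed, dtype=np.float64)
    return float((observed.sum() + a) / (observed.size + a + b))


def nan_replace(column: np.ndarray, mask: np.ndarray, fill_value: float = 0.0) -> np.ndarray:
    """Fill every missing cell with a constant (default 0)."""
    out = np.asarray(column, dtype=np.float64).copy()
    out[np.asarray(mask, dtype=bool)] = fill_value
    return out


def impute_dataset(table: ClinicalTable, policy: ImputationPolicy,
                   stats_rows: Optional[np.ndarray] = None) -> ClinicalTable:
    """Return a complete copy of ``table`` with every missing cell filled.

    Boolean columns follow ``policy.boolean_strategy``; continuous columns
    are mean-imputed.  Fill statistics come from the whole table by default
    (matching the impute-then-split protocol); pass ``stats_rows`` (e.g. the
    training indices) or set ``policy.train_only_statistics`` upstream for
    leakage-safe statistics restricted to those rows.
    """
    values = table.values.copy()
    mask = table.missing_mask
    rng = (np.random.default_rng(policy.seed)
           if policy.boolean_strategy in _STOCHASTIC else None)
    stat_sel = (np.asarray(stats_rows, dtype=np.int64)
                if stats_rows is not None else np.arange(table.n_rows))
    bool_cols = table.schema.boolean_columns()
    for j, name in enumerate(table.schema.feature_names):
        col, m = values[:, j], mask[:, j]
        if not m.any():
            continue
        # statistics restricted to stat_sel; fills applied to the full column
        stat_obs = col[stat_sel][~m[stat_sel]]
        if stat_obs.size == 0:
            raise AllMissingColumnError(f"column {name!r} has no observed values")
        if not bool_cols[j]:
            filled = col.copy()
            filled[m] = stat_obs.mean()
        elif policy.boolean_strategy == MODE:
            vals, counts = np.unique(stat_obs, return_counts=True)
            filled = col.copy()
            filled[m] = vals[np.argmax(counts)]
        elif policy.boolean_strategy == RANDOM:
            filled = col.copy()
            filled[m] = rng.choice(stat_obs, size=int(m.sum()), replace=True)
        elif policy.boolean_strategy == BAYESIAN:
            if not np.isin(stat_obs, (0.0, 1.0)).all():
                raise ValidationError(f"column {name!r} is not boolean")
            p1 = posterior_predictive_p1(stat_obs)
            filled = col.copy()
            filled[m] = (rng.random(int(m.sum())) < p1).astype(np.float64)
        else:  # NAN_REPLACE
            filled = nan_replace(col, m, policy.fill_value)
        values[:, j] = filled
    return ClinicalTable(values, np.zeros_like(mask), table.labels.copy(), table.schema)
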