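"""Training loop for max-minus negative regularized dropout.

One step feeds the positive batch through the dropout network twice and the
negative batch once, combines dual-pass cross-entropy, bidirectional KL
consistency and the (subtracted) negative regularizer into
``L = L_CE + alpha * (L_KL - L_NG)``, and applies one optimizer update.
Setting ``alpha = 0`` reduces the step to dual-pass cross-entropy;
``include_negative = False`` reduces it to R-Drop; both reductions are
exact, step for step, under shared seeds because each forward pass draws
its dropout masks from its own deterministically derived generator.

The module also provides the multi-trial evaluation protocol (five seeded
trials, mean and standard deviation of accuracy and F1) and the ablation
harness over imputation method, negative strategy, dropout rate, negative
loss form and alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import losses as L
from .backbone import Backbone, BackboneConfig, build_backbone, predict
from .data_model import ClinicalTable, FeatureSchema, stratified_split
from .evaluation import accuracy, confusion_matrix, f1_score
from .imputation import ImputationPolicy, impute_dataset
from .optim import build_optimizer
from .sampling import (IN_BATCH, MAX_MINUS, NEGATIVE_STRATEGIES, RANDOM_GENERATION,
                       MiniBatch, NegativeBatch, in_batch_negatives,
                       max_minus_negatives, random_generation_negatives)

ALPHA_SWEEP = (0.001, 0.01, 0.1, 1.0, 2.0, 4.0)
DROPOUT_SWEEP = (0.1, 0.2, 0.3, 0.4, 0.5)

NegativeFn = Callable[[MiniBatch, np.random.Generator], NegativeBatch]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the training protocol."""

    alpha: float = 2.0
    batch_size: int = 64
    epochs: int = 100
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    n_trials: int = 5
    base_seed: int = 0
    negative_strategy: str = MAX_MINUS
    negative_loss: str = "mse"
    include_negative: bool = True   # False reproduces R-Drop exactly

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if self.negative_strategy not in NEGATIVE_STRATEGIES:
            raise ValueError(f"unknown negative strategy {self.negative_strategy!r}")
        if self.negative_loss not in ("mse", "kl"):
            raise ValueError("negative_loss must be 'mse' or 'kl'")
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("invalid batch_size / epochs / learning_rate")


@dataclass
class TrainHistory:
    """Per-step loss components plus per-epoch test metrics."""

    steps: List[L.LossBreakdown] = field(default_factory=list)
    epoch_mean_total: List[float] = field(default_factory=list)
    epoch_accuracy: List[float] = field(default_factory=list)
    epoch_f1: List[float] = field(default_factory=list)

    def step_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"l_ce": s.l_ce, "l_kl": s.l_kl, "l_ng": s.l_ng,
                              "alpha": s.alpha, "total": s.total} for s in self.steps])

    def epoch_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": np.arange(len(self.epoch_accuracy)),
                             "mean_total_loss": self.epoch_mean_total,
                             "test_accuracy": self.epoch_accuracy,
                             "test_f1": self.epoch_f1})


def derive_rng(*key: int) -> np.random.Generator:
    """Deterministic per-purpose generator from a tuple of small integers.

    Every source of randomness in a run is derived this way from the base
    seed, so ablations and reduction tests can vary exactly one thing.
    """
    return np.random.default_rng(list(key))


def make_negative_fn(strategy: str, schema: Optional[FeatureSchema] = None,
                     dataset_matrix: Optional[np.ndarray] = None) -> NegativeFn:
    """Bind a negative-sampling strategy to the data it needs."""
    if strategy == MAX_MINUS:
        return lambda batch, rng: max_minus_negatives(batch)
    if strategy == IN_BATCH:
        return in_batch_negatives
    if strategy == RANDOM_GENERATION:
        if schema is None or dataset_matrix is None:
            raise ValueError("random_generation negatives need a schema and the "
                             "dataset matrix for collision checks")
        ranges = {}
        bool_cols = schema.boolean_columns()
        for j, name in enumerate(schema.feature_names):
            if not bool_cols[j]:
                col = dataset_matrix[:, j]
                ranges[name] = (float(col.min()), float(col.max()))
        bound_schema = replace(schema, continuous_ranges=ranges)
        return lambda batch, rng: random_generation_negatives(
            bound_schema, batch.x_b.shape[0], rng, dataset=dataset_matrix)
    raise ValueError(f"unknown negative strategy {strategy!r}")


def train_step(model: Backbone, batch: MiniBatch, config: TrainConfig,
               optimizer, step_key: Tuple[int, ...],
               negative_fn: Optional[NegativeFn] = None) -> L.LossBreakdown:
    """One optimizer update; returns the loss breakdown of the step.

    ``step_key`` seeds four independent generators (two positive dropout
    passes, negative sampling, negative dropout pass), so disabling the
    negative term never perturbs the positive passes.
    """
    rng_p1 = derive_rng(*step_key, 0)
    rng_p2 = derive_rng(*step_key, 1)
    p1 = model.forward(batch.x_b, rng_p1, train=True)
    p2 = model.forward(batch.x_b, rng_p2, train=True)
    y = np.asarray(batch.y_b, dtype=np.int64)

    ce = L.dual_cross_entropy(p1, p2, y)
    kl = L.bidirectional_kl(p1, p2)
    if config.include_negative:
        if negative_fn is None:
            negative_fn = make_negative_fn(config.negative_strategy)
        neg = negative_fn(batch, derive_rng(*step_key, 2))
        p_ng = model.forward(neg.x_ng, derive_rng(*step_key, 3), train=True)
        ng_fn = L.negative_mse if config.negative_loss == "mse" else L.negative_kl
        ng = ng_fn(p1, p2, p_ng)
        total = ce + config.alpha * (kl - ng)
        ng_value = float(ng.data)
    else:
        total = ce + config.alpha * kl
        ng_value = 0.0

    if not np.isfinite(total.data):
        raise RuntimeError(
            "non-finite loss; diagnostic: "
            f"p1 range [{p1.data.min():.3e}, {p1.data.max():.3e}], "
            f"p2 range [{p2.data.min():.3e}, {p2.data.max():.3e}], "
            f"ce={float(ce.data):.3e} kl={float(kl.data):.3e} ng={ng_value:.3e}")

    from .autodiff import zero_grads
    zero_grads(model.params)
    total.backward()
    optimizer.step()
    return L.LossBreakdown(l_ce=float(ce.data), l_kl=float(kl.data), l_ng=ng_value,
                           alpha=config.alpha, total=float(total.data))


def _evaluate(model: Backbone, table: ClinicalTable) -> Tuple[float, float]:
    probs = predict(model, table.values)
    y_pred = probs.argmax(axis=1)
    y_true = table.label_indices()
    k = table.schema.n_classes
    cm = confusion_matrix(y_true, y_pred, k)
    averaging = "binary" if k == 2 else "macro"
    return accuracy(cm), f1_score(cm, averaging=averaging)


def train(model: Backbone, train_table: ClinicalTable, test_table: ClinicalTable,
          config: TrainConfig) -> TrainHistory:
    """Epoch loop over shuffled mini-batches with per-epoch test evaluation."""
    for name, t in (("train", train_table), ("test", test_table)):
        if t.missing_mask.any():
            raise ValueError(f"{name} table still has missing cells; impute first")
    if train_table.n_rows == 0:
        raise ValueError("empty training set")
    x = train_table.values
    y = train_table.label_indices()
    n = x.shape[0]
    negative_fn = make_negative_fn(config.negative_strategy, train_table.schema, x)
    optimizer = build_optimizer(config.optimizer_name, model.params,
                                config.learning_rate)
    history = TrainHistory()
    for epoch in range(config.epochs):
        perm = derive_rng(config.base_seed, 1, epoch).permutation(n)
        totals = []
        for step, start in enumerate(range(0, n, config.batch_size)):
            idx = perm[start:start + config.batch_size]
            batch = MiniBatch(x[idx], y[idx])
            breakdown = train_step(model, batch, config, optimizer,
                                   (config.base_seed, 2, epoch, step), negative_fn)
            history.steps.append(breakdown)
            totals.append(breakdown.total)
        history.epoch_mean_total.append(float(np.mean(totals)))
        acc, f1 = _evaluate(model, test_table)
        history.epoch_accuracy.append(acc)
        history.epoch_f1.append(f1)
    return history


def standardize_continuous(train_table: ClinicalTable, test_table: ClinicalTable
                           ) -> Tuple[ClinicalTable, ClinicalTable]:
    """Z-score continuous columns with training-set statistics.

    Boolean columns stay 0/1 so the bit-flip reading of max-minus negatives
    is preserved; standardizing the continuous columns makes the two groups
    commensurate for both the network and the negative operator.
    """
    cont = train_table.schema.continuous_columns()
    mu = train_table.values[:, cont].mean(axis=0)
    sd = train_table.values[:, cont].std(axis=0)
    sd[sd == 0] = 1.0
    out = []
    for t in (train_table, test_table):
        v = t.values.copy()
        v[:, cont] = (v[:, cont] - mu) / sd
        out.append(ClinicalTable(v, t.missing_mask.copy(), t.labels.copy(), t.schema))
    return out[0], out[1]


def prepare_tables(dataset: ClinicalTable, policy: ImputationPolicy,
                   train_fraction: float, seed: int,
                   standardize: bool = True) -> Tuple[ClinicalTable, ClinicalTable]:
    """Impute, split and (optionally) standardize one dataset.

    Default order is impute-then-split with statistics from the full table;
    with ``policy.train_only_statistics`` the split happens first and the
    fill statistics are restricted to the training rows.
    """
    split = stratified_split(dataset, train_fraction, seed)
    stats_rows = split.train_indices if policy.train_only_statistics else None
    complete = impute_dataset(dataset, policy, stats_rows=stats_rows)
    train_t = complete.take_rows(split.train_indices)
    test_t = complete.take_rows(split.test_indices)
    if standardize:
        train_t, test_t = standardize_continuous(train_t, test_t)
    return train_t, test_t


@dataclass(frozen=True)
class TrialSummary:
    """Mean and standard deviation of final test metrics over seeded trials."""

    accuracy_mean: float
    accuracy_std: float
    f1_mean: float
    f1_std: float
    accuracies: Tuple[float, ...]
    f1_scores: Tuple[float, ...]


DataSource = Callable[[int], Tuple[ClinicalTable, ClinicalTable]]


def run_trials(config: TrainConfig, backbone_config: BackboneConfig,
               data_source: DataSource) -> TrialSummary:
    """Repeat train+evaluate ``n_trials`` times, differing only by seed.

    Trial t uses seed ``base_seed + t`` for the data split, the model
    initialization and every stochastic stage of training.
    """
    accs, f1s = [], []
    for t in range(config.n_trials):
        seed = config.base_seed + t
        train_t, test_t = data_source(seed)
        model = build_backbone(backbone_config, seed=seed)
        cfg = replace(config, base_seed=seed)
        history = train(model, train_t, test_t, cfg)
        if history.epoch_accuracy:
            accs.append(history.epoch_accuracy[-1])
            f1s.append(history.epoch_f1[-1])
        else:
            acc, f1 = _evaluate(model, test_t)
            accs.append(acc)
            f1s.append(f1)
    accs_a, f1s_a = np.array(accs), np.array(f1s)
    return TrialSummary(float(accs_a.mean()), float(accs_a.std()),
                        float(f1s_a.mean()), float(f1s_a.std()),
                        tuple(accs), tuple(f1s))


ABLATION_AXES = ("imputation", "negative_strategy", "dropout_rate",
                 "negative_loss", "alpha")

_DEFAULT_GRID = {
    "imputation": ("mode", "random", "bayesian", "nan_replace"),
    "negative_strategy": (RANDOM_GENERATION, IN_BATCH, MAX_MINUS),
    "dropout_rate": DROPOUT_SWEEP,
    "negative_loss": ("mse", "kl"),
    "alpha": ALPHA_SWEEP,
}


def run_ablation(axis: str, config: TrainConfig, backbone_config: BackboneConfig,
                 dataset: ClinicalTable, policy: ImputationPolicy,
                 train_fraction: float = 0.7,
                 values: Optional[Sequence] = None) -> pd.DataFrame:
    """Sweep one configuration axis, one multi-trial summary per grid point."""
    if axis not in ABLATION_AXES:
        raise ValueError(f"unknown ablation axis {axis!r}; expected one of {ABLATION_AXES}")
    values = tuple(values) if values is not None else _DEFAULT_GRID[axis]
    rows = []
    for value in values:
        cfg, bcfg, pol = config, backbone_config, policy
        if axis == "imputation":
            seed = policy.seed if policy.seed is not None else config.base_seed
            pol = replace(policy, boolean_strategy=value,
                          seed=seed if value in ("random", "bayesian") else policy.seed)
        elif axis == "negative_strategy":
            cfg = replace(config, negative_strategy=value)
        elif axis == "dropout_rate":
            bcfg = replace(backbone_config, dropout_rate=float(value))
        elif axis == "negative_loss":
            cfg = replace(config, negative_loss=value)
        elif axis == "alpha":
            cfg = replace(config, alpha=float(value))

        def source(seed: int, _pol=pol) -> Tuple[ClinicalTable, ClinicalTable]:
            return prepare_tables(dataset, _pol, train_fraction, seed)

        summary = run_trials(cfg, bcfg, source)
        rows.append({"axis": axis, "value": value,
                     "accuracy_mean": summary.accuracy_mean,
                     "accuracy_std": summary.accuracy_std,
                     "f1_mean": summary.f1_mean, "f1_std": summary.f1_std})
    return pd.DataFrame(rows)
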