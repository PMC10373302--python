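# maxminus-dropout

Training scheme for tabular clinical prediction under missing data:
**max-minus negative regularized dropout**. It targets the common clinical
setting — a table of mostly boolean symptom indicators plus a few continuous
measurements (age, course of treatment), a categorical diagnosis label, and
missing cells that must be imputed before a neural classifier can be
trained. Imputation introduces noise, and small clinical cohorts make the
resulting overfitting worse; this package trains the classifier with two
consistency regularizers that counteract it.

## The objective

At each step a mini-batch `x_b` is fed through the dropout network twice,
giving output distributions `P1(y|x, w)` and `P2(y|x, w)` from two random
sub-models. A *negative* batch is built by the max-minus operator

```
x_ng = max(x_b) − x_b
```

(per-feature column maximum over the current mini-batch), which on 0/1
symptom columns is a bit-flip and on mixed rows yields clinically
incoherent profiles belonging to no class. A third dropout pass gives
`P_ng(y|x_ng, w)`. One update minimizes

```
L = L_CE + α (L_KL − L_NG)

L_CE = mean_i [ −log P1(y_i) − log P2(y_i) ]             # both passes fit the label
L_KL = mean_i ½ [ KL(P1 ‖ P2) + KL(P2 ‖ P1) ]            # sub-model consistency
L_NG = mean_ij ( ½(P1 + P2) − P_ng )²_ij                 # pushed *up*: negatives differ
```

With `α = 0` this is dual-pass cross-entropy; without the `L_NG` term it is
R-Drop. Both reductions hold exactly, update for update, and are covered by
tests. `L_NG ≤ 1` on the probability simplex, so the subtracted term cannot
diverge.

The library also provides the surrounding protocol: mode / random /
Bayesian (Beta–Bernoulli) / constant-fill imputation for boolean features
and mean imputation for continuous ones, a stratified 70/30 split, the two
baseline negative-sampling strategies (in-batch class-mismatched rows,
schema-range random generation), confusion-matrix metrics (accuracy,
binary/macro F1), a five-trial evaluation protocol, an ablation harness
(imputation method, negative strategy, dropout rate, negative-loss form,
α), and a seeded synthetic clinical-data generator so everything runs
without downloads. The classifier backbone is pluggable: a depth-5 MLP
(hidden size 256) by default, with a small features-as-tokens transformer
encoder (embedding size 96) as an alternative; both run on the package's
own NumPy reverse-mode autodiff engine.

## Worked example

Generate the built-in clinical cohort profile (1,920 patients, 22 boolean
symptoms + age and course of treatment, 7 diabetes-syndrome classes, 275
missing boolean cells):

```
$ maxminus simulate --profile paper --out data.csv --seed 1
wrote 1920 rows x 24 features (275 missing cells) to data.csv
```

Run the standard learning benchmark from Python — five seeded trials of
mode-imputed, max-minus regularized training, against the same protocol
with the regularizer switched off:

```python
from maxminus_dropout.benchmark import run_benchmark

full = run_benchmark(base_seed=0, alpha=2.0, n_trials=5)
base = run_benchmark(base_seed=0, alpha=0.0, n_trials=5)
print(f"full method: {full.accuracy_mean:.4f} +- {full.accuracy_std:.4f}")
print(f"alpha=0    : {base.accuracy_mean:.4f} +- {base.accuracy_std:.4f}")
```

```
full method: 0.9806 +- 0.0074
alpha=0    : 0.9795 +- 0.0059
```

Each line is the mean and standard deviation of final test accuracy over
five trials differing only in seed; the Bayes-optimal ceiling of this
benchmark is ≈ 0.987 (`bayes_optimal_accuracy`), so both schemes sit close
to the ceiling and the regularized run does not trade accuracy away.
Config-driven experiments (`maxminus train|ablate|run --config cfg.yaml`)
write a history CSV, a metrics JSON and a manifest that reproduces the run
bit for bit.

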