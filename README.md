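# gdpsurv

Deep Cox proportional-hazards survival modelling with **group-lasso
regularization** for grouped, high-dimensional features — the situation of
multi-omics cancer cohorts, where a few hundred patients carry thousands
of molecular measurements and several measurements (expression, copy
number, protein level, mutation score) describe the same gene.

The model feeds the feature vector through two ReLU hidden layers into a
linear Cox risk score,

```
h1 = relu(W1 x + b1)       h2 = relu(W2 h1 + b2)       r(x) = βᵀ h2
λ(t|x) = λ0(t) · exp(r(x))
```

and trains by minibatch gradient descent on the regularized negative Cox
partial log-likelihood

```
C = − Σ_{i: event} [ r_i − log Σ_{j: tⱼ ≥ tᵢ} exp(r_j) ]
    + scale · ( α · Σ_l p_l‖W1⁽ˡ⁾‖₂ + (1−α) · ‖Wo‖₁ )
```

where `W1⁽ˡ⁾` is the block of first-layer weights attached to feature
group *l* (a gene), `p_l` the group size, and `Wo` the remaining weights.
The group norm zeroes out whole genes at once, which is what makes the
fit behave in the p ≫ n regime; ranking groups by first-layer weight mass
afterwards gives gene-level feature selection. Everything is implemented
in numpy with hand-derived backpropagation (verified against finite
differences); evaluation is by the concordance index (c-index), and a
classical linear Cox fit (via lifelines) serves as the comparator.

The package also ships the censored-data simulator used to benchmark all
of this (Weibull latent times, exponential censoring, equicorrelated
feature groups with known relevant groups) and a preprocessing pipeline
for raw mixed clinical/omics tables (missingness filter, mean imputation,
one-hot encoding, z-scoring, gene-level group map).

## Worked example

```python
from gdpsurv import (RegularizationConfig, SimulationConfig, simulate,
                     rank_features)
from gdpsurv.train import TrainingConfig, split, train

dataset, truth = simulate(SimulationConfig(
    n_samples=300, n_groups=50, group_size=4, n_relevant_groups=5,
    rng_seed=3))
splits = split(dataset.n_samples, seed=3)          # 60/20/20
reg = RegularizationConfig(scale=1.0, alpha=0.99,
                           group_map=dataset.group_map)
model, trace = train(dataset, reg, TrainingConfig(
    n_steps=600, eval_every=100, learning_rate=1e-3,
    optimizer_kind="adam_prox", hidden_sizes=(32, 16), rng_seed=3),
    splits=splits)
print(trace[["step", "train", "validation", "test"]].tail(1))
```

prints (from `examples/02_train_and_trace.py`)

```
 step    train  validation     test
  600 0.970550    0.846743 0.767617
```

— the c-index on the three partitions after 600 steps: the model ranks
97% of comparable training pairs correctly and generalizes far above the
0.5 chance level (validation 0.85), while the same run with `scale=0`
ends at a train–validation gap of 0.255 (memorization of the training
partition). The companion scripts in
`examples/` walk through simulation, training traces, gene ranking,
the deep-vs-linear-Cox comparison and table preprocessing, each printing
a few interpreted numbers.

A thin CLI mirrors the library (`gdpsurv simulate / prep / train /
gridsearch / evaluate / rank / compare / experiment / fixtures`); run
`gdpsurv --help`.

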