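"""Rank feature groups by first-layer weight mass after training.

The per-feature score sums the absolute first-layer weights across hidden
nodes; a group scores the maximum of its members.  On simulated data the
truly survival-relevant groups should surface at the top.
"""

from gdpsurv import RegularizationConfig, SimulationConfig, rank_features, simulate
from gdpsurv.train import TrainingConfig, train

dataset, truth = simulate(
    SimulationConfig(n_samples=300, n_groups=50, group_size=4, n_relevant_groups=5, rng_seed=5)
)
reg = RegularizationConfig(scale=1.0, alpha=0.99, group_map=dataset.group_map)
model, _ = train(
    dataset, reg,
    TrainingConfig(n_steps=800, eval_every=200, learning_rate=1e-3,
                   optimizer_kind="adam_prox", hidden_sizes=(32, 16), rng_seed=5),
)
table = rank_features(model, dataset.group_map)
print(table.head(10).to_string(index=False))
ranks = table.set_index("group_id").loc[list(truth.relevant_group_ids), "rank"]
print(f"\nranks of the 5 truly relevant groups: {sorted(ranks)}")
# Small ranks (well under the median 25) mean the first-layer weights
# concentrated on the groups that actually drive survival.
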