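"""Minibatch training of the deep Cox network, data splitting and grid search.

Each training step draws one random batch (default 50 samples, without
replacement within the batch) from the training partition, evaluates the
regularized negative partial log-likelihood with the risk set restricted
to the batch, and takes one optimizer step.  The concordance index on the
training / validation / test partitions is recorded along the way, giving
the characteristic trace: rapid overfitting of the training partition,
then — under a sufficiently strong penalty — a collapse of the first-layer
weights on irrelevant groups that closes the train/validation gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluate import c_index
from .model import (
    GDPModel,
    RegularizationConfig,
    cost_and_grads,
    forward,
    init_model,
)
from .simulate import SurvivalDataset

__all__ = ["TrainingConfig", "split", "train", "grid_search", "SplitIndices"]

logger = logging.getLogger(__name__)

DEFAULT_SCALE_GRID = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
DEFAULT_ALPHA_GRID = (0.5, 0.9, 0.95, 0.99)


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 50
    n_steps: int = 3000
    learning_rate: float = 1e-3
    optimizer_kind: str = "adam"  # "adam" | "sgd"
    eval_every: int = 1
    rng_seed: int = 0
    hidden_sizes: tuple[int, int] = (128, 64)
    norm_eps: float = 1e-8  # smoothing of the group norm inside the optimizer
    dtype: type = np.float64

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (a risk set needs a comparator)")
        if self.n_steps < 1 or self.eval_every < 1:
            raise ValueError("n_steps and eval_every must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer_kind not in ("adam", "sgd", "adam_prox"):
            raise ValueError("optimizer_kind must be 'adam', 'sgd' or 'adam_prox'")


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def split(
    n_or_dataset,
    fractions: tuple[float, ...] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitIndices:
    """Disjoint, exhaustive, seed-reproducible random partition.

    The default is the 60/20/20 train/validation/test split.  The
    cohort-style variant — hold out 20% for testing, then split the rest
    75/25 into training and cross-evaluation — is
    ``fractions=(0.8 * 0.75, 0.8 * 0.25, 0.2)``.
    """
    n = n_or_dataset if isinstance(n_or_dataset, (int, np.integer)) else n_or_dataset.n_samples
    fractions = tuple(fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three values summing to 1")
    perm = np.random.default_rng(seed).permutation(n)
    bounds = np.round(np.cumsum(fractions) * n).astype(int)
    parts = np.split(perm, bounds[:-1])
    if any(len(p) == 0 for p in parts):
        raise ValueError(f"n={n} too small for non-empty partitions {fractions}")
    return SplitIndices(train=parts[0], validation=parts[1], test=parts[2])


# weights decaying under the penalty approach zero geometrically; flushing
# magnitudes below this to exact zero keeps them out of the subnormal range
# (slow on most FPUs) and realizes the group sparsity the penalty drives at
_FLUSH = 1e-12


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p = params[k]
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
            np.copyto(p, 0.0, where=np.abs(p) < _FLUSH)
            np.copyto(m, 0.0, where=np.abs(m) < _FLUSH)


class _SGD:
    def __init__(self, params, lr: float):
        self.lr = lr

    def step(self, params, grads) -> None:
        for k, g in grads.items():
            p = params[k]
            p -= self.lr * g
            np.copyto(p, 0.0, where=np.abs(p) < _FLUSH)


def _prox_penalty(model: GDPModel, reg: RegularizationConfig, step_size: float) -> None:
    """Exact proximal operator of the penalty, applied after a likelihood step.

    Group soft-thresholding on W1 — each group's weight block shrinks in
    norm by ``step_size * scale * alpha * w_l`` and is zeroed outright when
    its norm falls below the threshold — and elementwise soft-thresholding
    on W2 and the output coefficients.  Realizes exact group sparsity
    instead of the oscillation a subgradient step produces around zero.
    """
    if reg.scale == 0:
        return
    tau_g = step_size * reg.scale * reg.alpha * reg.group_weights()
    sq = np.einsum("hf,hf->f", model.W1, model.W1)
    norms = np.sqrt(np.bincount(reg.group_map, weights=sq, minlength=reg.n_groups))
    factor = np.zeros_like(norms)
    nz = norms > 0
    factor[nz] = np.maximum(0.0, 1.0 - tau_g[nz] / norms[nz])
    model.W1 *= factor[reg.group_map].astype(model.W1.dtype)
    tau1 = step_size * reg.scale * (1.0 - reg.alpha)
    if tau1 > 0:
        for a in (model.W2, model.beta):
            np.copyto(a, np.sign(a) * np.maximum(np.abs(a) - tau1, 0.0))


def _partition_risks(model: GDPModel, ds: SurvivalDataset, splits: SplitIndices):
    risk = forward(model, ds.X)
    out = {}
    for name, idx in (("train", splits.train), ("validation", splits.validation), ("test", splits.test)):
        out[name] = c_index(risk[idx], ds.observed_time[idx], ds.event_status[idx])
    return out


def train(
    dataset: SurvivalDataset,
    reg: RegularizationConfig,
    config: TrainingConfig,
    splits: SplitIndices | None = None,
    model: GDPModel | None = None,
) -> tuple[GDPModel, pd.DataFrame]:
    """Train and return the final model plus the per-step c-index trace.

    The trace is a DataFrame with columns (step, batch_cost, train,
    validation, test); one row per ``eval_every`` steps.  Bit-identical
    given the same seed, data and config.
    """
    if splits is None:
        splits = split(dataset.n_samples, seed=config.rng_seed)
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(1)[0])
    dtype = config.dtype
    X = dataset.X.astype(dtype, copy=False)
    t_all = dataset.observed_time
    s_all = dataset.event_status
    if model is None:
        model = init_model(dataset.n_features, config.hidden_sizes, seed=config.rng_seed, dtype=dtype)
    else:
        model = model.copy()

    params = {"W1": model.W1, "b1": model.b1, "W2": model.W2, "b2": model.b2, "beta": model.beta}
    proximal = config.optimizer_kind == "adam_prox"
    opt_cls = _SGD if config.optimizer_kind == "sgd" else _Adam
    opt = opt_cls(params, config.learning_rate)
    grad_reg = replace(reg, scale=0.0) if proximal else reg

    tr_idx = splits.train
    n_tr = len(tr_idx)
    bs = min(config.batch_size, n_tr)
    records = []
    n_eventless = 0
    for step_i in range(1, config.n_steps + 1):
        batch = tr_idx[rng.choice(n_tr, size=bs, replace=False)]
        if s_all[batch].sum() == 0:
            n_eventless += 1
        c, grads = cost_and_grads(
            model, X[batch], t_all[batch], s_all[batch], grad_reg, eps=config.norm_eps
        )
        opt.step(params, grads)
        if proximal:
            _prox_penalty(model, reg, config.learning_rate)
        if step_i % config.eval_every == 0 or step_i == config.n_steps:
            ci = _partition_risks(model, dataset, splits)
            records.append(
                {
                    "step": step_i,
                    "batch_cost": c,
                    "train": ci["train"],
                    "validation": ci["validation"],
                    "test": ci["test"],
                }
            )
            logger.info(
                "step %d cost %.4f c-index train %.3f val %.3f test %.3f",
                step_i, c, ci["train"], ci["validation"], ci["test"],
            )
    if n_eventless:
        logger.warning("%d batches contained no events (likelihood gradient zero)", n_eventless)
    trace = pd.DataFrame.from_records(records)
    return model, trace


def grid_search(
    dataset: SurvivalDataset,
    reg_template: RegularizationConfig,
    config: TrainingConfig,
    scale_grid=DEFAULT_SCALE_GRID,
    alpha_grid=DEFAULT_ALPHA_GRID,
    splits: SplitIndices | None = None,
    select: str = "last",  # "last" | "best_validation"
) -> tuple[pd.DataFrame, dict]:
    """Train one model per (scale, alpha) cell; rank cells by validation c-index.

    Every cell gets a fresh seed-derived initialization.  Returns the full
    table and the best cell (ties broken toward smaller scale, then smaller
    alpha).  A failed cell is recorded with a missing score.
    """
    scale_grid = list(scale_grid)
    alpha_grid = list(alpha_grid)
    if not scale_grid or not alpha_grid:
        raise ValueError("grids must be non-empty")
    if splits is None:
        splits = split(dataset.n_samples, seed=config.rng_seed)
    rows = []
    for ci_cell, (scale, alpha) in enumerate(
        (s, a) for s in sorted(scale_grid) for a in sorted(alpha_grid)
    ):
        reg = replace(reg_template, scale=scale, alpha=alpha)
        cell_cfg = replace(config, rng_seed=config.rng_seed + 1000 * (ci_cell + 1))
        try:
            mdl, trace = train(dataset, reg, cell_cfg, splits=splits)
            if select == "best_validation":
                score = float(trace["validation"].max())
            else:
                score = float(trace["validation"].iloc[-1])
        except Exception as exc:
            logger.warning("grid cell scale=%g alpha=%g failed: %s", scale, alpha, exc)
            score = np.nan
        rows.append({"scale": scale, "alpha": alpha, "validation_cindex": score})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["validation_cindex"])
    if ok.empty:
        raise RuntimeError("every grid cell failed")
    # argmax with ties toward smaller scale then smaller alpha
    best_row = ok.sort_values(
        ["validation_cindex", "scale", "alpha"], ascending=[False, True, True]
    ).iloc[0]
    best = {
        "scale": float(best_row["scale"]),
        "alpha": float(best_row["alpha"]),
        "validation_cindex": float(best_row["validation_cindex"]),
    }
    return table, best
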