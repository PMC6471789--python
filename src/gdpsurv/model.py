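"""The deep Cox proportional-hazards network with group-lasso regularization.

Architecture: two fully connected ReLU hidden layers feed a linear Cox
risk score, ``risk = beta' H2`` with ``H1 = relu(W1 x + b1)`` and
``H2 = relu(W2 H1 + b2)``.  The hazard is ``lambda(t|x) =
lambda0(t) exp(risk)``; the baseline hazard cancels from the partial
likelihood, so training needs only the risk scores.

The training objective is

    C = -l(beta) + scale * ( alpha * sum_l w_l ||W1_l||_2
                             + (1 - alpha) * ||Wo||_1 )

where ``l`` is the Cox partial log-likelihood with Breslow tie handling,
``W1_l`` collects every first-layer weight touching a feature of group
``l``, ``w_l`` is the group weight (the group size ``p_l`` by default;
``sqrt(p_l)`` optionally), and ``Wo`` is every other trainable weight
(``W2`` and the output coefficients; biases are unpenalized).  Gradients
are computed by explicit backpropagation in numpy and checked against
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "GDPModel",
    "RegularizationConfig",
    "init_model",
    "forward",
    "cox_partial_loglik",
    "cox_partial_loglik_grad",
    "group_lasso_penalty",
    "penalty_grads",
    "cost",
    "cost_and_grads",
    "breslow_baseline",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class GDPModel:
    """Weights and biases of the two hidden layers plus the Cox output vector."""

    W1: np.ndarray  # (hidden1, n_features)
    b1: np.ndarray  # (hidden1,)
    W2: np.ndarray  # (hidden2, hidden1)
    b2: np.ndarray  # (hidden2,)
    beta: np.ndarray  # (hidden2,)

    def __post_init__(self) -> None:
        h1, p = self.W1.shape
        h2 = self.W2.shape[0]
        if self.W2.shape != (h2, h1) or self.b1.shape != (h1,):
            raise ValueError("inconsistent layer shapes")
        if self.b2.shape != (h2,) or self.beta.shape != (h2,):
            raise ValueError("inconsistent layer shapes")
        for a in (self.W1, self.b1, self.W2, self.b2, self.beta):
            if not np.all(np.isfinite(a)):
                raise ValueError("model parameters must be finite")

    @property
    def n_features(self) -> int:
        return self.W1.shape[1]

    @property
    def hidden_sizes(self) -> tuple[int, int]:
        return self.W1.shape[0], self.W2.shape[0]

    def copy(self) -> "GDPModel":
        return GDPModel(*(a.copy() for a in (self.W1, self.b1, self.W2, self.b2, self.beta)))


@dataclass
class RegularizationConfig:
    """Penalty strength ``scale``, group-lasso mixing ``alpha`` and the grouping.

    ``alpha=1`` is pure group lasso on the first layer, ``alpha=0`` pure l1
    on the remaining weights; intermediate values mix the two.  ``group_map``
    assigns each input feature to a group; ``group_weight`` selects whether
    a group's norm is weighted by its size ``p_l`` (the default, the form
    the objective is stated in) or by ``sqrt(p_l)`` (the conventional
    group-lasso weighting).
    """

    scale: float
    alpha: float
    group_map: np.ndarray
    group_weight: Literal["p", "sqrt_p"] = "p"
    group_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("scale must be non-negative")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        self.group_map = np.asarray(self.group_map, dtype=int)
        sizes = np.bincount(self.group_map)
        if self.group_sizes is None:
            self.group_sizes = sizes
        elif not np.array_equal(np.asarray(self.group_sizes, dtype=int), sizes):
            raise ValueError("group_sizes inconsistent with group_map")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def group_weights(self) -> np.ndarray:
        p = self.group_sizes.astype(float)
        return p if self.group_weight == "p" else np.sqrt(p)


def init_model(
    n_features: int,
    hidden_sizes: tuple[int, int] = (128, 64),
    seed: int = 0,
    dtype=np.float64,
) -> GDPModel:
    """He-uniform initialization for the ReLU layers; zero biases and output.

    With a zero output vector the initial risk score is identically zero,
    so an untrained model predicts at chance (c-index 0.5 under the
    tied-risk convention).
    """
    h1, h2 = hidden_sizes
    rng = np.random.default_rng(seed)
    lim1 = np.sqrt(6.0 / n_features)
    lim2 = np.sqrt(6.0 / h1)
    return GDPModel(
        W1=rng.uniform(-lim1, lim1, size=(h1, n_features)).astype(dtype),
        b1=np.zeros(h1, dtype=dtype),
        W2=rng.uniform(-lim2, lim2, size=(h2, h1)).astype(dtype),
        b2=np.zeros(h2, dtype=dtype),
        beta=np.zeros(h2, dtype=dtype),
    )


def _forward_cached(model: GDPModel, X: np.ndarray):
    Z1 = X @ model.W1.T + model.b1
    H1 = np.maximum(Z1, 0.0)
    Z2 = H1 @ model.W2.T + model.b2
    H2 = np.maximum(Z2, 0.0)
    risk = H2 @ model.beta
    return risk, H1, H2, Z1 > 0, Z2 > 0


def forward(model: GDPModel, X: np.ndarray) -> np.ndarray:
    """Per-sample risk score ``beta' relu(W2 relu(W1 x + b1) + b2)``."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {model.n_features}"
        )
    return _forward_cached(model, X)[0]


# ---------------------------------------------------------------------------
# Cox partial log-likelihood (Breslow risk sets: all j with t_j >= t_i)

def _check_outcomes(risk, time, status):
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    if not (risk.shape == time.shape == status.shape) or risk.ndim != 1:
        raise ValueError("risk, time, status must be equal-length vectors")
    if not np.isin(status, (0, 1)).all():
        raise ValueError("status must be binary (0/1)")
    return risk, time, status.astype(float)


def _tie_blocks(t_desc: np.ndarray):
    """first/last index of each tie block in a descending-sorted time vector."""
    n = len(t_desc)
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = t_desc[1:] != t_desc[:-1]
    block_id = np.cumsum(change) - 1
    starts = np.flatnonzero(change)
    ends = np.r_[starts[1:] - 1, n - 1]
    return starts[block_id], ends[block_id]


def cox_partial_loglik(risk, time, status) -> float:
    """Sum over events of ``risk_i - log sum_{t_j >= t_i} exp(risk_j)``.

    The risk set includes the event itself and every sample whose observed
    time ties it.  Log-sum-exp is accumulated in log space, so large risk
    scores do not overflow.  Returns 0 when there are no events.
    """
    risk, time, status = _check_outcomes(risk, time, status)
    if status.sum() == 0:
        return 0.0
    order = np.argsort(-time, kind="stable")
    r, s = risk[order], status[order]
    _, last = _tie_blocks(time[order])
    log_denom = np.logaddexp.accumulate(r)[last]
    return float(np.sum(s * (r - log_denom)))


def cox_partial_loglik_grad(risk, time, status) -> np.ndarray:
    """Gradient of the partial log-likelihood with respect to the risk scores."""
    risk, time, status = _check_outcomes(risk, time, status)
    n = len(risk)
    if status.sum() == 0:
        return np.zeros(n)
    order = np.argsort(-time, kind="stable")
    r, s = risk[order], status[order]
    first, last = _tie_blocks(time[order])
    log_denom = np.logaddexp.accumulate(r)[last]
    # A_k = sum over events i with t_i <= t_k of 1/denom_i  (suffix sum)
    w = s * np.exp(-log_denom)
    suffix = np.cumsum(w[::-1])[::-1]
    A = suffix[first]
    g_sorted = s - np.exp(r) * A
    g = np.empty(n)
    g[order] = g_sorted
    return g


# ---------------------------------------------------------------------------
# penalty

def group_lasso_penalty(model: GDPModel, reg: RegularizationConfig, eps: float = 0.0) -> float:
    """Mixed group-lasso / l1 penalty.

    ``eps > 0`` substitutes the smoothed norm ``sqrt(sum w^2 + eps^2)`` used
    by the optimizer; the default reports the exact norm.
    """
    if reg.scale == 0:
        return 0.0
    sq_per_feature = np.einsum("hf,hf->f", model.W1, model.W1)
    group_sq = np.bincount(reg.group_map, weights=sq_per_feature, minlength=reg.n_groups)
    norms = np.sqrt(group_sq + eps * eps)
    gl = float(reg.group_weights() @ norms)
    l1 = float(np.abs(model.W2).sum() + np.abs(model.beta).sum())
    return reg.scale * (reg.alpha * gl + (1.0 - reg.alpha) * l1)


def penalty_grads(model: GDPModel, reg: RegularizationConfig, eps: float = 1e-8):
    """Gradients (subgradients at kinks) of the penalty for W1, W2 and beta."""
    if reg.scale == 0:
        z = np.zeros_like
        return z(model.W1), z(model.W2), z(model.beta)
    sq_per_feature = np.einsum("hf,hf->f", model.W1, model.W1)
    group_sq = np.bincount(reg.group_map, weights=sq_per_feature, minlength=reg.n_groups)
    inv = reg.group_weights() / np.sqrt(group_sq + eps * eps)
    gW1 = reg.scale * reg.alpha * model.W1 * inv[reg.group_map]
    c = reg.scale * (1.0 - reg.alpha)
    return gW1, c * np.sign(model.W2), c * np.sign(model.beta)


# ---------------------------------------------------------------------------
# cost and gradients

def cost(model: GDPModel, X, time, status, reg: RegularizationConfig, eps: float = 0.0) -> float:
    """Negative partial log-likelihood plus the regularization penalty."""
    risk = forward(model, X)
    return -cox_partial_loglik(risk, time, status) + group_lasso_penalty(model, reg, eps=eps)


def cost_and_grads(model: GDPModel, X, time, status, reg: RegularizationConfig, eps: float = 1e-8):
    """Cost (with eps-smoothed penalty) and its gradient for every parameter.

    Returns ``(cost_value, grads)`` with ``grads`` keyed like the model
    fields.  The likelihood term vanishes (zero gradient) for a batch with
    no events; the penalty gradient still applies.
    """
    X = np.asarray(X)
    risk, H1, H2, m1, m2 = _forward_cached(model, X)
    ll = cox_partial_loglik(risk, time, status)
    d_risk = -cox_partial_loglik_grad(risk, time, status)  # d(-l)/d risk

    gBeta = H2.T @ d_risk
    dH2 = np.outer(d_risk, model.beta)
    dZ2 = dH2 * m2
    gW2 = dZ2.T @ H1
    gb2 = dZ2.sum(axis=0)
    dZ1 = (dZ2 @ model.W2) * m1
    gW1 = dZ1.T @ X
    gb1 = dZ1.sum(axis=0)

    pW1, pW2, pBeta = penalty_grads(model, reg, eps=eps)
    grads = {
        "W1": gW1 + pW1,
        "b1": gb1,
        "W2": gW2 + pW2,
        "b2": gb2,
        "beta": gBeta + pBeta,
    }
    c = -ll + group_lasso_penalty(model, reg, eps=eps)
    return c, grads


# ---------------------------------------------------------------------------
# baseline hazard

def breslow_baseline(risk, time, status):
    """Breslow step estimate of the cumulative baseline hazard.

    Returns ``(event_times, cum_hazard)``: at each distinct event time the
    cumulative hazard increases by (number of events there) divided by the
    sum of ``exp(risk)`` over samples still at risk.  With all risks zero
    this reduces to the Nelson-Aalen estimator.
    """
    risk, time, status = _check_outcomes(risk, time, status)
    order = np.argsort(-time, kind="stable")
    r, t, s = risk[order], time[order], status[order]
    _, last = _tie_blocks(t)
    denom_all = np.cumsum(np.exp(r))[last]
    ev = s == 1
    if not ev.any():
        return np.array([]), np.array([])
    ev_times, inverse, counts = np.unique(t[ev], return_inverse=True, return_counts=True)
    # one denominator per distinct event time (same within a tie block)
    denom = np.zeros(len(ev_times))
    denom[inverse] = denom_all[ev]
    increments = counts / denom
    return ev_times, np.cumsum(increments)


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(path: str | Path, model: GDPModel, reg: RegularizationConfig | None = None) -> None:
    """Self-describing single-file checkpoint (numpy .npz archive)."""
    meta: dict = {"hidden_sizes": list(model.hidden_sizes), "n_features": model.n_features}
    arrays = {"W1": model.W1, "b1": model.b1, "W2": model.W2, "b2": model.b2, "beta": model.beta}
    if reg is not None:
        meta["reg"] = {"scale": reg.scale, "alpha": reg.alpha, "group_weight": reg.group_weight}
        arrays["group_map"] = reg.group_map
    np.savez(path, meta=np.bytes_(json.dumps(meta).encode()), **arrays)


def load_checkpoint(path: str | Path) -> tuple[GDPModel, RegularizationConfig | None]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        model = GDPModel(z["W1"], z["b1"], z["W2"], z["b2"], z["beta"])
        reg = None
        if "reg" in meta:
            reg = RegularizationConfig(
                scale=meta["reg"]["scale"],
                alpha=meta["reg"]["alpha"],
                group_map=z["group_map"],
                group_weight=meta["reg"]["group_weight"],
            )
    return model, reg
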