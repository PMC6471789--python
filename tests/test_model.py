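"""Network forward pass, Cox partial likelihood, penalty, cost gradients
and the Breslow baseline — each against hand computations or brute-force
oracles."""

import numpy as np
import pytest

from gdpsurv import (
    GDPModel,
    RegularizationConfig,
    cost,
    cost_and_grads,
    cox_partial_loglik,
    forward,
    group_lasso_penalty,
    init_model,
    load_checkpoint,
    save_checkpoint,
)
from gdpsurv.model import breslow_baseline, cox_partial_loglik_grad, penalty_grads


def _zero_model(p, h1=3, h2=2):
    return GDPModel(
        W1=np.zeros((h1, p)), b1=np.zeros(h1), W2=np.zeros((h2, h1)),
        b2=np.zeros(h2), beta=np.zeros(h2),
    )


# ---------------------------------------------------------------- forward

def test_forward_zero_weights_gives_zero_risk(rng):
    m = _zero_model(4)
    X = rng.standard_normal((7, 4))
    assert np.array_equal(forward(m, X), np.zeros(7))


def test_forward_relu_kills_negative_preactivation():
    m = GDPModel(W1=np.array([[1.0]]), b1=np.zeros(1), W2=np.array([[1.0]]),
                 b2=np.zeros(1), beta=np.array([1.0]))
    assert forward(m, np.array([[-5.0]]))[0] == 0.0
    assert forward(m, np.array([[2.0]]))[0] == 2.0


def test_forward_matches_hand_chain():
    """Two features, hand-set weights; chain computed by hand:
    x=(1,-1); z1 = W1 x + b1 = (0.5*1 - 0.25*(-1) + 0.1, -1*1 + 0*(-1) - 0.2)
       = (0.85, -1.2) -> h1 = (0.85, 0)
    z2 = 2*0.85 - 0 + 0.05 = 1.75 -> h2 = 1.75; risk = -0.5*1.75 = -0.875."""
    m = GDPModel(
        W1=np.array([[0.5, -0.25], [-1.0, 0.0]]),
        b1=np.array([0.1, -0.2]),
        W2=np.array([[2.0, -3.0]]),
        b2=np.array([0.05]),
        beta=np.array([-0.5]),
    )
    out = forward(m, np.array([[1.0, -1.0]]))
    assert out[0] == pytest.approx(-0.875, abs=1e-12)


def test_forward_rejects_shape_mismatch(rng):
    m = _zero_model(4)
    with pytest.raises(ValueError, match="columns"):
        forward(m, rng.standard_normal((3, 5)))


def test_model_rejects_nonfinite():
    with pytest.raises(ValueError, match="finite"):
        GDPModel(W1=np.array([[np.inf]]), b1=np.zeros(1), W2=np.ones((1, 1)),
                 b2=np.zeros(1), beta=np.zeros(1))


# ------------------------------------------------- partial log-likelihood

def test_loglik_two_sample_hand_value():
    """times (1,2), both events, zero risks: l = -log 2."""
    ll = cox_partial_loglik([0.0, 0.0], [1.0, 2.0], [1, 1])
    assert ll == pytest.approx(-np.log(2), abs=1e-12)


def test_loglik_no_events_is_zero():
    assert cox_partial_loglik([1.0, 2.0], [1.0, 2.0], [0, 0]) == 0.0


def test_loglik_single_event_alone_in_risk_set():
    # the latest time with an event contributes r - log(e^r) = 0
    assert cox_partial_loglik([3.7], [5.0], [1]) == pytest.approx(0.0, abs=1e-12)


def test_loglik_rejects_nonbinary_status():
    with pytest.raises(ValueError, match="binary"):
        cox_partial_loglik([0.0], [1.0], [2])


def test_loglik_shift_invariance(censored_case):
    risk, time, status = censored_case
    a = cox_partial_loglik(risk, time, status)
    b = cox_partial_loglik(risk + 123.456, time, status)
    assert abs(a - b) < 1e-8


def _brute_force_loglik(risk, time, status):
    ll = 0.0
    for i in range(len(risk)):
        if status[i] == 1:
            rs = [np.exp(risk[j]) for j in range(len(risk)) if time[j] >= time[i]]
            ll += risk[i] - np.log(sum(rs))
    return ll


@pytest.mark.parametrize("seed", range(5))
def test_loglik_matches_risk_set_enumeration(seed):
    """Explicit enumeration of risk sets on small instances, with ties."""
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 20)
    risk = rng.standard_normal(n)
    time = rng.integers(1, 8, n).astype(float)  # integer times force ties
    status = rng.integers(0, 2, n)
    assert cox_partial_loglik(risk, time, status) == pytest.approx(
        _brute_force_loglik(risk, time, status), abs=1e-10
    )


def test_loglik_grad_matches_finite_differences(censored_case):
    risk, time, status = censored_case
    g = cox_partial_loglik_grad(risk, time, status)
    h = 1e-6
    for k in range(0, len(risk), 7):
        r2 = risk.copy(); r2[k] += h
        r3 = risk.copy(); r3[k] -= h
        num = (cox_partial_loglik(r2, time, status) - cox_partial_loglik(r3, time, status)) / (2 * h)
        assert g[k] == pytest.approx(num, abs=1e-5)


# ----------------------------------------------------------------- penalty

def _toy_reg(alpha, scale, group_map=(0, 0)):
    return RegularizationConfig(scale=scale, alpha=alpha, group_map=np.array(group_map))


def test_penalty_zero_scale(rng):
    m = init_model(2, (3, 2), seed=0)
    m.W1[:] = rng.standard_normal(m.W1.shape)
    assert group_lasso_penalty(m, _toy_reg(0.7, 0.0)) == 0.0


def test_penalty_hand_value_group_branch():
    """One group of 2 features, 2 hidden nodes, all W1 entries 1, alpha 1:
    penalty = p_l * ||W1||_2 = 2 * sqrt(4) = 4."""
    m = GDPModel(W1=np.ones((2, 2)), b1=np.zeros(2), W2=np.zeros((1, 2)),
                 b2=np.zeros(1), beta=np.zeros(1))
    assert group_lasso_penalty(m, _toy_reg(1.0, 1.0)) == pytest.approx(4.0, abs=1e-12)


def test_penalty_pure_l1_branch():
    m = GDPModel(W1=np.full((2, 2), 9.0), b1=np.zeros(2), W2=np.array([[1.0, -2.0]]),
                 b2=np.zeros(1), beta=np.zeros(1))
    assert group_lasso_penalty(m, _toy_reg(0.0, 1.0)) == pytest.approx(3.0, abs=1e-12)


def test_penalty_positive_homogeneity(rng):
    m = init_model(6, (4, 3), seed=1)
    m.beta[:] = rng.standard_normal(3)
    reg = RegularizationConfig(scale=2.0, alpha=0.6, group_map=np.array([0, 0, 1, 1, 2, 2]))
    p1 = group_lasso_penalty(m, reg)
    m2 = m.copy()
    for a in (m2.W1, m2.W2, m2.beta):
        a *= 2.0
    assert group_lasso_penalty(m2, reg) == pytest.approx(2 * p1, rel=1e-12)


def test_penalty_singleton_groups_reduce_to_l1(rng):
    """With every group of size 1 (p_l = 1) the group term is an l1 norm on W1."""
    p = 5
    m = init_model(p, (3, 2), seed=2)
    reg = RegularizationConfig(scale=1.0, alpha=1.0, group_map=np.arange(p))
    # per-feature l2 over hidden nodes, not plain |w|: groups span the column
    expected = np.sqrt((m.W1**2).sum(axis=0)).sum()
    assert group_lasso_penalty(m, reg) == pytest.approx(expected, rel=1e-12)
    # and with a single hidden node it is exactly the l1 norm
    m1 = init_model(p, (1, 2), seed=3)
    assert group_lasso_penalty(m1, RegularizationConfig(1.0, 1.0, np.arange(p))) == pytest.approx(
        np.abs(m1.W1).sum(), rel=1e-12
    )


def test_penalty_rejects_bad_alpha():
    with pytest.raises(ValueError, match="alpha"):
        _toy_reg(1.5, 1.0)


def test_group_weight_sqrt_option():
    m = GDPModel(W1=np.ones((2, 2)), b1=np.zeros(2), W2=np.zeros((1, 2)),
                 b2=np.zeros(1), beta=np.zeros(1))
    reg = RegularizationConfig(scale=1.0, alpha=1.0, group_map=np.array([0, 0]),
                               group_weight="sqrt_p")
    assert group_lasso_penalty(m, reg) == pytest.approx(np.sqrt(2) * 2.0, rel=1e-12)


# -------------------------------------------------------------------- cost

def test_cost_composition_two_sample():
    m = _zero_model(3)
    X = np.eye(3)[:2]
    c = cost(m, X, np.array([1.0, 2.0]), np.array([1, 1]), _toy_reg(0.5, 0.0, (0, 1, 2)))
    assert c == pytest.approx(np.log(2), abs=1e-12)


def test_cost_no_events_zero_scale(rng):
    m = init_model(3, (2, 2), seed=0)
    X = rng.standard_normal((4, 3))
    c = cost(m, X, np.ones(4), np.zeros(4, dtype=int), _toy_reg(0.5, 0.0, (0, 1, 2)))
    assert c == 0.0


def test_cost_penalty_strictly_increases(rng, small_sim):
    ds, _ = small_sim
    m = init_model(ds.n_features, (8, 4), seed=1)
    m.beta[:] = rng.standard_normal(4)
    reg0 = RegularizationConfig(scale=0.0, alpha=0.9, group_map=ds.group_map)
    reg1 = RegularizationConfig(scale=1.0, alpha=0.9, group_map=ds.group_map)
    c0 = cost(m, ds.X, ds.observed_time, ds.event_status, reg0)
    c1 = cost(m, ds.X, ds.observed_time, ds.event_status, reg1)
    assert c1 > c0


def test_cost_gradients_match_finite_differences(rng):
    """Full backprop vs central differences at a random parameter point."""
    n, p = 15, 6
    X = rng.standard_normal((n, p))
    time = rng.uniform(1, 10, n)
    status = rng.integers(0, 2, n)
    status[:2] = 1
    reg = RegularizationConfig(scale=0.8, alpha=0.6, group_map=np.array([0, 0, 1, 1, 2, 2]))
    m = init_model(p, (5, 4), seed=7)
    m.beta[:] = rng.standard_normal(4) * 0.5
    m.b1[:] = rng.standard_normal(5) * 0.1
    eps = 1e-8
    _, grads = cost_and_grads(m, X, time, status, reg, eps=eps)
    h = 1e-6
    for field in ("W1", "b1", "W2", "b2", "beta"):
        a = getattr(m, field)
        for _ in range(10):
            idx = tuple(rng.integers(0, d) for d in a.shape)
            a[idx] += h
            cp = cost(m, X, time, status, reg, eps=eps)
            a[idx] -= 2 * h
            cm = cost(m, X, time, status, reg, eps=eps)
            a[idx] += h
            num = (cp - cm) / (2 * h)
            ana = grads[field][idx]
            assert abs(num - ana) <= 1e-4 * max(1.0, abs(num), abs(ana)), field


def test_penalty_gradient_at_group_origin():
    """A group sitting exactly at zero: the eps-smoothed gradient is zero
    (the subgradient chosen at the kink) and stays finite."""
    m = _zero_model(4, h1=2, h2=2)
    reg = RegularizationConfig(scale=1.0, alpha=1.0, group_map=np.array([0, 0, 1, 1]))
    gW1, _, _ = penalty_grads(m, reg, eps=1e-8)
    assert np.all(gW1 == 0.0)
    assert np.all(np.isfinite(gW1))


# ----------------------------------------------------------------- breslow

def test_breslow_reduces_to_nelson_aalen():
    """All risks zero, distinct event times: increments 1/n, 1/(n-1), ..."""
    n = 5
    times = np.arange(1.0, n + 1)
    t, H = breslow_baseline(np.zeros(n), times, np.ones(n, dtype=int))
    expected = np.cumsum(1.0 / np.arange(n, 0, -1.0))
    assert np.allclose(H, expected, atol=1e-12)
    assert np.array_equal(t, times)


def test_breslow_single_event():
    t, H = breslow_baseline(np.zeros(1), np.array([3.0]), np.array([1]))
    assert np.array_equal(t, [3.0]) and H[0] == pytest.approx(1.0)


def test_breslow_hand_computed():
    """Three samples, risks (log2, 0, 0), times (1,2,3), all events.
    H(1) = 1/(2+1+1) = 0.25; H(2) = 0.25 + 1/2; H(3) = 0.75 + 1/1."""
    risk = np.array([np.log(2.0), 0.0, 0.0])
    t, H = breslow_baseline(risk, np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
    assert np.allclose(H, [0.25, 0.75, 1.75], atol=1e-12)


def test_breslow_monotone(censored_case):
    risk, time, status = censored_case
    _, H = breslow_baseline(risk, time, status)
    assert np.all(np.diff(H) >= 0)


# ------------------------------------------------------------- checkpoints

def test_checkpoint_round_trip(tmp_path, rng):
    m = init_model(6, (4, 3), seed=5)
    m.beta[:] = rng.standard_normal(3)
    reg = RegularizationConfig(scale=2.0, alpha=0.95, group_map=np.array([0, 0, 1, 1, 2, 2]))
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, m, reg)
    m2, reg2 = load_checkpoint(path)
    for a, b in zip((m.W1, m.b1, m.W2, m.b2, m.beta), (m2.W1, m2.b1, m2.W2, m2.b2, m2.beta)):
        assert np.array_equal(a, b)
    assert reg2.scale == reg.scale and reg2.alpha == reg.alpha
    assert np.array_equal(reg2.group_map, reg.group_map)
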