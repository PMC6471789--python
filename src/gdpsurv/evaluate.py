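"""Concordance index, classical Cox comparator, replicate comparisons and
first-layer feature ranking.

The concordance index (c-index) is the fraction of comparable sample pairs
whose predicted risk ordering matches the observed survival ordering.  A
pair (i, j) is comparable iff sample i had an event and its observed time
is strictly shorter than j's; tied observed times are not comparable, and
tied risk scores count one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import GDPModel
from .simulate import SurvivalDataset

__all__ = [
    "c_index",
    "comparable_pairs",
    "fit_cph_baseline",
    "compare_methods",
    "rank_features",
    "WelchResult",
]


def comparable_pairs(time, status) -> int:
    """Number of comparable ordered pairs Q under the censoring rule."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    ev = status == 1
    # pair (i, j) comparable iff status_i = 1 and t_i < t_j
    return int((time[ev][:, None] < time[None, :]).sum())


def c_index(risk, time, status) -> float:
    """Concordance between risk scores and censored survival times.

    Higher risk must pair with shorter event time; tied risks contribute
    0.5.  Raises when no pair is comparable (e.g. all samples censored).
    """
    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    status = np.asarray(status)
    if not (risk.shape == time.shape == status.shape) or risk.ndim != 1:
        raise ValueError("risk, time, status must be equal-length vectors")
    ev = status == 1
    comp = time[ev][:, None] < time[None, :]  # (events, all)
    Q = int(comp.sum())
    if Q == 0:
        raise ValueError("no comparable pairs (all samples censored or all times tied)")
    r_ev = risk[ev][:, None]
    concordant = (r_ev > risk[None, :]) & comp
    tied = (r_ev == risk[None, :]) & comp
    return float((concordant.sum() + 0.5 * tied.sum()) / Q)


def fit_cph_baseline(
    train: SurvivalDataset,
    test: SurvivalDataset,
    penalizer: float = 1e-4,
) -> tuple[float, np.ndarray]:
    """Fit a classical linear Cox model and score the test set.

    The fit maximizes the standard Cox partial likelihood (Newton-Raphson,
    via lifelines) with a small ridge penalizer for numerical stability in
    near-collinear designs.  Returns the test c-index and the fitted
    coefficient vector.
    """
    from lifelines import CoxPHFitter

    df = pd.DataFrame(train.X, columns=train.feature_names)
    df["time"] = train.observed_time
    df["status"] = train.event_status
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="time", event_col="status")
    except Exception as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    beta_hat = cph.params_.to_numpy()
    test_risk = test.X @ beta_hat
    return c_index(test_risk, test.observed_time, test.event_status), beta_hat


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    dof: float
    p_value: float


def compare_methods(scores_a, scores_b, sided: str = "two") -> WelchResult:
    """Welch (unequal-variance) t-test between two arms of replicate c-indices.

    ``sided='one'`` tests the alternative mean(A) > mean(B).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per arm")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both arms: t-test degenerate")
    alternative = {"two": "two-sided", "one": "greater"}[sided]
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def rank_features(model: GDPModel, group_map) -> pd.DataFrame:
    """Rank feature groups by first-layer weight mass.

    Per-feature score: sum over first-hidden-layer nodes of the absolute
    incoming weight.  Per-group score: the maximum over member features.
    Returns a DataFrame (group_id, score, rank) sorted by rank; ties are
    broken by group id.
    """
    group_map = np.asarray(group_map, dtype=int)
    if group_map.shape != (model.n_features,):
        raise ValueError("group_map length must equal the model's feature count")
    per_feature = np.abs(model.W1).sum(axis=0)
    n_groups = int(group_map.max()) + 1
    group_score = np.full(n_groups, -np.inf)
    np.maximum.at(group_score, group_map, per_feature)
    group_score[group_score == -np.inf] = 0.0
    order = np.lexsort((np.arange(n_groups), -group_score))
    ranks = np.empty(n_groups, dtype=int)
    ranks[order] = np.arange(1, n_groups + 1)
    return (
        pd.DataFrame({"group_id": np.arange(n_groups), "score": group_score, "rank": ranks})
        .sort_values("rank")
        .reset_index(drop=True)
    )
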