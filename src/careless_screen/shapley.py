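"""Shapley-value explanations of classifier predictions.

The Shapley value of variable i for an instance x is the weighted average
of its marginal contributions over all subsets S of the other variables:

    phi_i = sum_{S subseteq F\\{i}} |S|! (|F|-|S|-1)! / |F|!
            * [ f_{S u {i}}(x_{S u {i}}) - f_S(x_S) ]

The value function f_S is the model's expected output when the variables
in S are fixed at x's values and the remaining variables are integrated
over a background sample (interventional averaging). ``exact_shapley``
enumerates every subset (feasible up to ~15 variables); ``sampled_shapley``
is the unbiased permutation Monte-Carlo estimator used at questionnaire
scale, reporting a per-variable standard error.

Explanations are computed on the model's probability of the positive
(careless) class: a positive phi pushes the prediction toward careless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PREDICTION_GROUPS = ("TP", "FP", "TN", "FN")


@dataclass
class ShapleyProblem:
    """One instance to explain against a model and a background sample."""

    predict: Callable[[np.ndarray], np.ndarray]  # batched row matrix -> outputs
    x: np.ndarray                                # (p,)
    background: np.ndarray                       # (m, p)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.background = np.atleast_2d(np.asarray(self.background, dtype=float))
        if self.x.ndim != 1 or self.x.size < 1:
            raise ValueError("x must be a non-empty 1-d vector")
        if self.background.shape[1] != self.x.size:
            raise ValueError("background width differs from x")
        if self.background.shape[0] < 1:
            raise ValueError("background must be non-empty")

    @property
    def n_features(self) -> int:
        return self.x.size


def exact_shapley(problem: ShapleyProblem, max_features: int = 15) -> np.ndarray:
    """Exact Shapley values by full subset enumeration.

    Evaluates v(S) = mean over background rows b of f(x_S, b_outside_S)
    for every S, then applies the weighted-subset sum. Limited to
    ``max_features`` variables (2^p subsets).
    """
    p = problem.n_features
    if p > max_features:
        raise ValueError(f"{p} variables exceed the enumeration limit "
                         f"({max_features}); use sampled_shapley")
    m = problem.background.shape[0]
    n_subsets = 1 << p

    # batch all subset matrices into one model call (chunked)
    v = np.empty(n_subsets)
    chunk = max(1, 200_000 // m)
    for start in range(0, n_subsets, chunk):
        stop = min(start + chunk, n_subsets)
        Z = np.empty(((stop - start) * m, p))
        for k, mask in enumerate(range(start, stop)):
            block = problem.background.copy()
            for i in range(p):
                if mask >> i & 1:
                    block[:, i] = problem.x[i]
            Z[k * m:(k + 1) * m] = block
        out = np.asarray(problem.predict(Z), dtype=float)
        v[start:stop] = out.reshape(stop - start, m).mean(axis=1)

    fact = [factorial(k) for k in range(p + 1)]
    phi = np.zeros(p)
    for mask in range(n_subsets):
        s = int(mask).bit_count()
        for i in range(p):
            if mask >> i & 1:
                continue
            w = fact[s] * fact[p - s - 1] / fact[p]
            phi[i] += w * (v[mask | (1 << i)] - v[mask])
    return phi


def sampled_shapley(problem: ShapleyProblem, n_samples: int,
                    seed: int | None = None,
                    chunk_size: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Permutation Monte-Carlo Shapley estimate with standard errors.

    Each sample draws a random variable ordering and one background row;
    walking through the ordering, the change in model output when a
    variable switches from the background value to x's value is that
    variable's marginal contribution. The estimator is unbiased for
    ``exact_shapley``; returns (phi, se) with per-variable standard error
    sd/sqrt(n_samples).
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    p = problem.n_features
    m = problem.background.shape[0]

    sums = np.zeros(p)
    sq_sums = np.zeros(p)
    done = 0
    while done < n_samples:
        take = min(chunk_size, n_samples - done)
        perms = rng.permuted(np.tile(np.arange(p), (take, 1)), axis=1)
        bg = problem.background[rng.integers(0, m, size=take)]
        # rows[t, j] = background row t with the first j permuted vars set to x
        rows = np.empty((take, p + 1, p))
        rows[:, 0, :] = bg
        t_idx = np.arange(take)
        for j in range(1, p + 1):
            rows[:, j, :] = rows[:, j - 1, :]
            idx = perms[:, j - 1]
            rows[t_idx, j, idx] = problem.x[idx]
        out = np.asarray(problem.predict(rows.reshape(-1, p)), dtype=float)
        out = out.reshape(take, p + 1)
        marg = np.diff(out, axis=1)  # marg[t, j] -> variable perms[t, j]
        contrib = np.zeros((take, p))
        contrib[np.arange(take)[:, None], perms] = marg
        sums += contrib.sum(axis=0)
        sq_sums += (contrib ** 2).sum(axis=0)
        done += take

    phi = sums / n_samples
    var = (sq_sums - n_samples * phi ** 2) / (n_samples - 1)
    se = np.sqrt(np.clip(var, 0.0, None) / n_samples)
    return phi, se


# ---------------------------------------------------------------------------
# prediction-outcome groups and contribution records
# ---------------------------------------------------------------------------

def tag_prediction_groups(model, X, labels, threshold: float = 0.5
                          ) -> np.ndarray:
    """TP/FP/TN/FN tag per respondent (careless = positive class)."""
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if callable(model) and not hasattr(model, "predict_proba_careless"):
        scores = np.asarray(model(X), dtype=float)
    else:
        scores = model.predict_proba_careless(X)
    pred = (scores >= threshold).astype(int)
    out = np.where(pred == 1, np.where(labels == 1, "TP", "FP"),
                   np.where(labels == 0, "TN", "FN"))
    return out.astype(object)


def contribution_records(model, X: pd.DataFrame, labels,
                         background: pd.DataFrame,
                         n_samples: int = 200, seed: int = 0,
                         threshold: float = 0.5,
                         exact_limit: int = 12) -> pd.DataFrame:
    """Per-respondent Shapley contributions plus prediction-group tags.

    Wide frame: ``respondent``, ``group``, ``model_output``, then one phi
    column per variable. Small problems (<= ``exact_limit`` variables)
    are enumerated exactly; larger ones use the permutation estimator
    with a per-respondent derived seed.
    """
    labels = np.asarray(labels)
    groups = tag_prediction_groups(model, X, labels, threshold)
    outputs = model.predict_proba_careless(X)
    bg = background.to_numpy(dtype=float)
    cols = list(X.columns)

    def predict_fn(Z: np.ndarray) -> np.ndarray:
        return model.predict_proba_careless(
            pd.DataFrame(Z, columns=cols))

    rows = []
    for i in range(len(X)):
        prob = ShapleyProblem(predict=predict_fn,
                              x=X.iloc[i].to_numpy(dtype=float),
                              background=bg)
        if len(cols) <= exact_limit:
            phi = exact_shapley(prob)
        else:
            phi, _ = sampled_shapley(prob, n_samples=n_samples,
                                     seed=(seed + i) % (2 ** 31))
        rows.append(phi)
    phis = pd.DataFrame(np.vstack(rows), columns=cols)
    meta = pd.DataFrame({"respondent": X.index.to_numpy(),
                         "group": groups, "model_output": outputs})
    return pd.concat([meta.reset_index(drop=True), phis], axis=1)


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

@dataclass
class ContributionSummary:
    """Per-variable mean contribution with 95% CI, by prediction group."""

    table: pd.DataFrame   # variable, group, mean, ci_lo, ci_hi, n

    def group_frame(self, group: str) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group]
        if sub.empty:
            raise KeyError(f"group {group!r} not summarized")
        return sub.set_index("variable")

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def delta(self, group_a: str, group_b: str) -> pd.Series:
        """|mean difference| per variable between two groups."""
        a = self.group_frame(group_a)["mean"]
        b = self.group_frame(group_b)["mean"]
        return (a - b).abs().rename("delta_contribution")


def summarize_group_contributions(records: pd.DataFrame,
                                  groups: Sequence[str] | None = None
                                  ) -> ContributionSummary:
    """Mean phi and normal-approximation 95% CI per variable and group.

    ``groups=None`` summarizes over all respondents under the pseudo-group
    ``"all"`` (used for the with/without-indices stability criterion).
    Empty requested groups are skipped with a logged warning.
    """
    var_cols = [c for c in records.columns
                if c not in ("respondent", "group", "model_output")]
    rows = []
    if groups is None:
        frames = [("all", records)]
    else:
        frames = []
        for g in groups:
            sub = records[records["group"] == g]
            if sub.empty:
                logger.warning("prediction group %s is empty; skipped", g)
                continue
            frames.append((g, sub))
    for g, sub in frames:
        n = len(sub)
        means = sub[var_cols].mean()
        sds = sub[var_cols].std(ddof=1).fillna(0.0) if n > 1 else \
            pd.Series(0.0, index=var_cols)
        ses = sds / np.sqrt(n)
        for v in var_cols:
            rows.append({"variable": v, "group": g,
                         "mean": float(means[v]),
                         "ci_lo": float(means[v] - 1.96 * ses[v]),
                         "ci_hi": float(means[v] + 1.96 * ses[v]),
                         "n": n})
    return ContributionSummary(table=pd.DataFrame(rows))
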