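"""Weak-sampling learner: hierarchical Bayesian logistic regression.

The learner treats training as supervised classification: each sentence is a
binary-indicator vector (its item, its slot, and the item×slot pair, plus an
intercept) and the label is grammatical (1) or ungrammatical (0).  Nothing in
the model refers to how sentences were sampled, so an item×slot pair that
never occurs contributes no likelihood at all: its pair coefficient stays at
the prior mode (zero) and the prediction for that cell is carried entirely by
the item and slot main effects.  That is what makes the model blind to
indirect negative evidence.

The hierarchy is realized as zero-mean Gaussian priors with a separate scale
per feature family (items, slots, pairs); the scales are selected on a finite
grid by Laplace-approximated marginal likelihood, and the coefficients are
the MAP under the selected scales.  Everything is deterministic.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .corpus import TrainingTrial
from .language import Gram, LanguageSpec

__all__ = [
    "WeakPrior",
    "WeakPosterior",
    "ConvergenceError",
    "encode_features",
    "feature_names",
    "fit_weak",
    "fit_weak_counts",
    "grammaticality_prob_weak",
    "direction",
]


class ConvergenceError(RuntimeError):
    """MAP optimization failed to reach the required gradient tolerance."""


@dataclass(frozen=True)
class WeakPrior:
    """Group-wise Gaussian prior scales and their selection grids.

    Each non-intercept feature family (item, slot, pair indicators) has a
    zero-mean Gaussian prior whose standard deviation is chosen from
    ``scale_grid`` by maximizing the Laplace-approximated marginal
    likelihood.  The intercept gets a fixed broad prior.
    """

    scale_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    intercept_scale: float = 10.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scale_grid) or self.intercept_scale <= 0:
            raise ValueError("prior scales must be strictly positive")


@dataclass(frozen=True)
class WeakPosterior:
    """MAP coefficients with Laplace curvature and the selected prior scales."""

    items: tuple[str, ...]
    slots: tuple[str, ...]
    coef: np.ndarray  # MAP point estimate, ordered as feature_names()
    cov: np.ndarray  # inverse Hessian at the MAP (Laplace covariance)
    scales: dict[str, float]  # selected prior scale per feature family
    log_evidence: float
    degenerate_labels: bool  # True if training carried only one label

    def names(self) -> list[str]:
        return feature_names(self.items, self.slots)

    def to_json(self) -> str:
        payload = {
            "coefficients": dict(
                zip(self.names(), (float(c) for c in self.coef))
            ),
            "coef_sd": dict(
                zip(self.names(), (float(s) for s in np.sqrt(np.diag(self.cov))))
            ),
            "prior_scales": self.scales,
            "log_evidence": float(self.log_evidence),
            "degenerate_labels": self.degenerate_labels,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def feature_names(items: Sequence[str], slots: Sequence[str]) -> list[str]:
    return (
        ["intercept"]
        + [f"item:{i}" for i in items]
        + [f"slot:{s}" for s in slots]
        + [f"pair:{i}|{s}" for i in items for s in slots]
    )


def _group_slices(n_items: int, n_slots: int) -> dict[str, slice]:
    a = 1
    b = a + n_items
    c = b + n_slots
    d = c + n_items * n_slots
    return {
        "intercept": slice(0, 1),
        "item": slice(a, b),
        "slot": slice(b, c),
        "pair": slice(c, d),
    }


def encode_features(item: str, slot: str, spec: LanguageSpec) -> np.ndarray:
    """Binary indicator vector for a sentence of the given cell.

    Layout: [intercept | item indicators | slot indicators | pair indicators];
    exactly three non-intercept entries are 1.
    """
    if item not in spec.items:
        raise ValueError(f"unknown item {item!r}")
    if slot not in spec.slots:
        raise ValueError(f"unknown slot {slot!r}")
    n_i, n_s = len(spec.items), len(spec.slots)
    x = np.zeros(1 + n_i + n_s + n_i * n_s)
    x[0] = 1.0
    i = spec.items.index(item)
    s = spec.slots.index(slot)
    x[1 + i] = 1.0
    x[1 + n_i + s] = 1.0
    x[1 + n_i + n_s + i * n_s + s] = 1.0
    return x


def _neg_log_posterior(w, X, y, n, prior_var):
    z = X @ w
    # weighted Bernoulli log-likelihood: y successes of n at each design row
    ll = y * z - n * np.logaddexp(0.0, z)
    lp = -0.5 * np.sum(w * w / prior_var)
    return -(ll.sum() + lp)


def _grad(w, X, y, n, prior_var):
    p = 1.0 / (1.0 + np.exp(-(X @ w)))
    return -(X.T @ (y - n * p)) + w / prior_var


def _hess(w, X, y, n, prior_var):
    p = 1.0 / (1.0 + np.exp(-(X @ w)))
    W = n * p * (1.0 - p)
    return (X.T * W) @ X + np.diag(1.0 / prior_var)


def _map_fit(X, y, n, prior_var, gtol: float = 1e-9, max_iter: int = 500):
    w0 = np.zeros(X.shape[1])
    res = minimize(
        _neg_log_posterior,
        w0,
        args=(X, y, n, prior_var),
        jac=_grad,
        hess=_hess,
        method="trust-exact",
        options={"gtol": gtol / 10, "maxiter": max_iter},
    )
    w = res.x
    # polish with Newton steps; the objective is strictly convex
    for _ in range(50):
        g = _grad(w, X, y, n, prior_var)
        if np.linalg.norm(g) < 1e-10:
            break
        w = w - np.linalg.solve(_hess(w, X, y, n, prior_var), g)
    g = _grad(w, X, y, n, prior_var)
    if np.linalg.norm(g) > 1e-8:
        raise ConvergenceError(
            f"MAP gradient norm {np.linalg.norm(g):.3e} above tolerance 1e-8 "
            f"after {max_iter} iterations"
        )
    return w


def _log_evidence(w, X, y, n, prior_var):
    H = _hess(w, X, y, n, prior_var)
    sign, logdet = np.linalg.slogdet(H)
    d = len(w)
    log_joint = -_neg_log_posterior(w, X, y, n, prior_var) - 0.5 * np.sum(
        np.log(2 * np.pi * prior_var)
    )
    return log_joint + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet


def _aggregate(trials: Iterable[TrainingTrial]) -> dict[tuple[str, str], list[int]]:
    agg: dict[tuple[str, str], list[int]] = {}
    for t in trials:
        cell = (t.sentence.item, t.sentence.slot)
        succ_fail = agg.setdefault(cell, [0, 0])
        if t.label is Gram.GRAMMATICAL:
            succ_fail[0] += 1
        elif t.label is Gram.UNGRAMMATICAL:
            succ_fail[1] += 1
        else:
            raise ValueError(f"trial for cell {cell} carries a withheld label")
    return agg


def fit_weak(
    trials: Sequence[TrainingTrial],
    prior: WeakPrior | None = None,
    spec: LanguageSpec | None = None,
) -> WeakPosterior:
    """Fit the group-prior logistic regression to labeled trials.

    Both labels should be present; an all-one-label corpus is accepted but
    flagged via ``degenerate_labels`` (the prior keeps the fit finite).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("weak learner needs at least one labeled trial")
    if spec is not None:
        items, slots = spec.items, spec.slots
    else:
        items = tuple(sorted({t.sentence.item for t in trials}))
        slots = tuple(sorted({t.sentence.slot for t in trials}))
    agg = _aggregate(trials)
    cells = sorted(agg)
    counts = np.array([[agg[c][0], agg[c][0] + agg[c][1]] for c in cells], dtype=float)
    return fit_weak_counts(cells, counts[:, 0], counts[:, 1], items, slots, prior)


def fit_weak_counts(
    cells: Sequence[tuple[str, str]],
    successes: np.ndarray,
    totals: np.ndarray,
    items: Sequence[str],
    slots: Sequence[str],
    prior: WeakPrior | None = None,
) -> WeakPosterior:
    """Fit from per-cell (grammatical, total) counts — the sufficient statistic."""
    if prior is None:
        prior = WeakPrior()
    items, slots = tuple(items), tuple(slots)

    class _Mini:  # minimal item/slot carrier for encode_features
        pass

    mini = _Mini()
    mini.items, mini.slots = items, slots
    X = np.array([encode_features(i, s, mini) for i, s in cells])
    y = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    degenerate = bool(np.all(y == n) or np.all(y == 0))

    groups = _group_slices(len(items), len(slots))
    d = X.shape[1]

    best = None
    for si, ss, sp in itertools.product(
        prior.scale_grid, prior.scale_grid, prior.scale_grid
    ):
        prior_var = np.empty(d)
        prior_var[groups["intercept"]] = prior.intercept_scale**2
        prior_var[groups["item"]] = si**2
        prior_var[groups["slot"]] = ss**2
        prior_var[groups["pair"]] = sp**2
        w = _map_fit(X, y, n, prior_var)
        ev = _log_evidence(w, X, y, n, prior_var)
        if best is None or ev > best[0]:
            best = (ev, w, prior_var, {"item": si, "slot": ss, "pair": sp})

    ev, w, prior_var, scales = best
    cov = np.linalg.inv(_hess(w, X, y, n, prior_var))
    return WeakPosterior(
        items=items,
        slots=slots,
        coef=w,
        cov=cov,
        scales={"intercept": prior.intercept_scale, **scales},
        log_evidence=ev,
        degenerate_labels=degenerate,
    )


def grammaticality_prob_weak(
    post: WeakPosterior, item: str, slot: str, spec: LanguageSpec | None = None
) -> float:
    """Predicted probability that a sentence of this cell is grammatical."""

    class _Mini:
        pass

    mini = _Mini()
    mini.items, mini.slots = post.items, post.slots
    x = encode_features(item, slot, mini)
    z = float(x @ post.coef)
    return float(1.0 / (1.0 + np.exp(-z)))


def direction(prob: float) -> str:
    """Classify a probability as grammatical/ungrammatical; 0.5 is undetermined."""
    if prob > 0.5:
        return "grammatical"
    if prob < 0.5:
        return "ungrammatical"
    return "undetermined"
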