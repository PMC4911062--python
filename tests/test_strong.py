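"""Strong-sampling learner: conjugacy, quadrature agreement, and the
indirect-negative-evidence behavior."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from samplearn.corpus import generate_training_sequence
from samplearn.language import Gram
from samplearn.strong import (
    StrongHyper,
    fit_strong,
    fit_strong_counts,
    grammaticality_score_strong,
    predictive_slot_dist,
    simplex_grid,
)


def _dirmult_predictive(counts, alpha, beta):
    """Closed-form posterior predictive with hyperparameters pinned."""
    counts = np.asarray(counts, dtype=float)
    num = counts + alpha * np.asarray(beta)
    return num / num.sum(axis=1, keepdims=True)


@pytest.mark.parametrize(
    "counts,alpha,beta",
    [
        ([[10, 0, 0]], 1.0, (1 / 3, 1 / 3, 1 / 3)),
        ([[10, 0, 0]], 1.0, (0.2, 0.5, 0.3)),
        ([[3, 4, 5], [0, 0, 7]], 2.5, (0.6, 0.3, 0.1)),
        ([[0, 0]], 0.7, (0.25, 0.75)),  # no observations -> prior predictive
    ],
)
def test_conjugacy_oracle(counts, alpha, beta):
    """With alpha and beta fixed, the fit equals the Dirichlet-multinomial
    posterior predictive in closed form."""
    counts = np.asarray(counts, dtype=float)
    items = [f"i{k}" for k in range(counts.shape[0])]
    slots = [f"s{k}" for k in range(counts.shape[1])]
    post = fit_strong_counts(
        counts, items, slots, StrongHyper(fixed_alpha=alpha, fixed_beta=beta)
    )
    expected = _dirmult_predictive(counts, alpha, beta)
    assert np.allclose(post.predictive, expected, atol=1e-9)
    # the documented worked value for the single-item case
    if counts.tolist() == [[10, 0, 0]] and beta[0] == pytest.approx(1 / 3):
        assert post.predictive[0, 0] == pytest.approx((10 + 1 / 3) / 11, abs=1e-9)


def test_quadrature_oracle_two_by_two():
    """Grid marginalization matches continuous integration over the base
    distribution on a 2-item, 2-slot toy to 1e-3."""
    counts = np.array([[6.0, 2.0], [5.0, 0.0]])
    alpha_grid = (0.1, 0.5, 1.0, 3.0, 10.0)
    scale = 5.0
    hyper = StrongHyper(alpha_grid=alpha_grid, alpha_prior_scale=scale)
    post = fit_strong_counts(counts, ["i0", "i1"], ["A", "B"], hyper)

    alphas = np.asarray(alpha_grid)
    w_alpha = np.exp(-alphas / scale) * np.gradient(alphas)
    totals = counts.sum(axis=1)

    def loglik(b, a):
        ab = a * np.array([b, 1.0 - b])
        ll = 0.0
        for i in range(2):
            ll += gammaln(a) - gammaln(a + totals[i])
            ll += np.sum(gammaln(ab + counts[i]) - gammaln(ab))
        return ll

    num = np.zeros((2, 2))
    den = 0.0
    for a, wa in zip(alphas, w_alpha):
        z = quad(lambda b: np.exp(loglik(b, a)), 0.0, 1.0, limit=200)[0]
        den += wa * z
        for i in range(2):
            for s in range(2):

                def f(b, i=i, s=s, a=a):
                    beta = np.array([b, 1.0 - b])
                    pred = (counts[i, s] + a * beta[s]) / (totals[i] + a)
                    return np.exp(loglik(b, a)) * pred

                num[i, s] += wa * quad(f, 0.0, 1.0, limit=200)[0]
    expected = num / den
    expected /= expected.sum(axis=1, keepdims=True)
    assert np.allclose(post.predictive, expected, atol=1e-3)


def test_simplex_grid_properties():
    g = simplex_grid(3, 12)
    assert np.allclose(g.sum(axis=1), 1.0)
    assert g.min() > 0
    assert len(g) == 55  # C(11, 2) interior compositions


def test_fit_requires_positive_evidence_only(exp1):
    trials = generate_training_sequence(exp1, seed=0)
    with pytest.raises(ValueError, match="positive evidence"):
        fit_strong(trials, spec=exp1)
    with pytest.raises(ValueError, match="at least one"):
        fit_strong([], spec=exp1)


def test_exp1_predictive_pattern(predictions, exp1):
    post = predictions["exp1"]["strong_post"]
    # the exception slot gets near-zero predictive mass for V4 (the shared
    # base distribution keeps it slightly above the never-grammatical C3)
    v4 = predictive_slot_dist(post, "V4")
    assert np.argmax(v4) == exp1.slots.index("C1")
    assert v4[exp1.slots.index("C2")] < 0.05
    # V2 was only ever heard in C2: mass concentrates there
    v2 = predictive_slot_dist(post, "V2")
    assert np.argmax(v2) == exp1.slots.index("C2")
    assert v2[exp1.slots.index("C2")] > 0.9
    # predictive rows are proper, fully supported distributions
    assert np.allclose(post.predictive.sum(axis=1), 1.0, atol=1e-9)
    assert post.predictive.min() > 0


def test_symmetric_counts_give_uniform_predictive():
    post = fit_strong_counts(np.full((2, 3), 5.0), ["a", "b"], ["x", "y", "z"])
    assert np.allclose(post.predictive, 1 / 3, atol=1e-9)


def test_score_normalization(predictions, exp1):
    post = predictions["exp1"]["strong_post"]
    # modal slot scores exactly 1
    for item in exp1.items:
        row = predictive_slot_dist(post, item)
        modal = exp1.slots[int(np.argmax(row))]
        assert grammaticality_score_strong(post, item, modal) == pytest.approx(1.0)
    # both slots of the alternating verb are near-equally acceptable
    assert grammaticality_score_strong(post, "V1", "C1") > 0.5
    assert grammaticality_score_strong(post, "V1", "C2") > 0.5
    # exception cell scored far below the acceptance midpoint
    assert grammaticality_score_strong(post, "V4", "C2") < 0.5
    with pytest.raises(KeyError):
        grammaticality_score_strong(post, "V9", "C1")


def test_predictive_monotone_in_observations():
    rng = np.random.default_rng(0)
    for _ in range(10):
        counts = rng.integers(0, 12, size=(3, 3)).astype(float)
        base = fit_strong_counts(counts, list("abc"), list("xyz"))
        i, s = rng.integers(0, 3, size=2)
        bumped_counts = counts.copy()
        bumped_counts[i, s] += 1
        bumped = fit_strong_counts(bumped_counts, list("abc"), list("xyz"))
        assert bumped.predictive[i, s] >= base.predictive[i, s] - 1e-12


def test_exchangeability(exp1):
    trials = [
        t
        for t in generate_training_sequence(exp1, seed=4)
        if t.label is Gram.GRAMMATICAL
    ]
    post_a = fit_strong(trials, spec=exp1)
    post_b = fit_strong(list(reversed(trials)), spec=exp1)
    assert np.allclose(post_a.predictive, post_b.predictive, atol=0)


@pytest.mark.parametrize("fixture", ["exp1", "exp2", "exp3"])
def test_exception_score_decreases_with_replication(specs, predictions, fixture):
    """Replicating the corpus strengthens the indirect negative evidence."""
    spec = specs[fixture]
    counts = predictions[fixture]["strong_post"].counts
    scores = []
    for k in (1, 2, 4):
        post = fit_strong_counts(k * counts, spec.items, spec.slots)
        scores.append(grammaticality_score_strong(post, *spec.exception_cell))
    assert scores[0] > scores[1] > scores[2]
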