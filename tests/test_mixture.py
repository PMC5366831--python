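"""Gaussian mixture primitives: densities, moments, reliability, learning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from avwgmm.mixture import (LearningRates, Mixture, apply_winner_take_all,
                            central_tendency, component_likelihood,
                            component_posterior, cue_weight,
                            cue_weight_pairwise, gradient_deltas,
                            mixture_likelihood, variability)
from conftest import random_mixture


def test_component_likelihood_matches_scipy_and_edge_cases():
    # standard-normal peak
    assert component_likelihood(0.0, 0.0, 1.0, 1.0) == pytest.approx(
        1.0 / np.sqrt(2 * np.pi), rel=1e-12)
    # zero-frequency component contributes exactly nothing
    assert component_likelihood(5.0, 0.0, 1.0, 0.0) == 0.0
    # phi-scaled density agrees with an independent evaluation
    assert component_likelihood(1.0, 0.0, 2.0, 0.5) == pytest.approx(
        0.5 * stats.norm.pdf(1.0, 0.0, 2.0), rel=1e-12)
    with pytest.raises(ValueError):
        component_likelihood(np.nan, 0.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        component_likelihood(0.0, 0.0, -1.0, 1.0)


def test_mixture_likelihood_is_sum_of_components(rng):
    m = random_mixture(rng, K=5)
    for x in rng.normal(0, 5, 10):
        brute = sum(component_likelihood(x, m.mu[j], m.sigma[j], m.phi[j])
                    for j in range(m.K))
        assert mixture_likelihood(x, m) == pytest.approx(brute, rel=1e-12)
    # two half-weight copies of a component match one full-weight component
    one = Mixture([0.0], [1.0], [1.0])
    two = Mixture([0.0, 0.0], [1.0, 1.0], [0.5, 0.5])
    for x in (-2.0, 0.0, 1.3):
        assert mixture_likelihood(x, two) == pytest.approx(
            mixture_likelihood(x, one), rel=1e-12)


def test_component_posterior_normalizes_and_handles_underflow(rng):
    m = random_mixture(rng, K=5)
    post = component_posterior(0.7, m)
    dens = np.array([component_likelihood(0.7, m.mu[j], m.sigma[j], m.phi[j])
                     for j in range(m.K)])
    np.testing.assert_allclose(post, dens / dens.sum(), rtol=1e-12)
    assert post.sum() == pytest.approx(1.0)
    # single component takes all responsibility
    single = Mixture([3.0], [2.0], [1.0])
    assert component_posterior(-50.0, single, 0) == 1.0
    # two components symmetric about x split it evenly
    sym = Mixture([-1.0, 1.0], [1.0, 1.0], [0.5, 0.5])
    assert component_posterior(0.0, sym, 0) == pytest.approx(0.5)
    # total underflow: uniform over components above the phi floor
    far = Mixture([0.0, 1.0], [1e-3, 1e-3], [1.0 - 1e-6, 1e-6])
    with np.errstate(under="ignore"):
        post = component_posterior(1e6, far)
    np.testing.assert_allclose(post, [1.0, 0.0])


def test_central_tendency_and_variability(rng):
    two = Mixture([0.0, 10.0], [1.0, 1.0], [0.5, 0.5])
    assert central_tendency(two) == pytest.approx(5.0)
    assert central_tendency(Mixture([7.0], [2.0], [1.0])) == 7.0
    assert variability(Mixture([0.0], [2.0], [1.0])) == pytest.approx(4.0)
    # between-component spread only (sigma at the floor)
    narrow = Mixture([-1.0, 1.0], [1e-3, 1e-3], [0.5, 0.5])
    assert variability(narrow) == pytest.approx(1.0, abs=1e-5)
    # brute-force weighted mean on a large random mixture
    m = random_mixture(rng, K=50)
    assert central_tendency(m) == pytest.approx(
        float(np.sum(m.mu * m.phi) / np.sum(m.phi)), rel=1e-12)
    assert min(m.mu) <= central_tendency(m) <= max(m.mu)
    with pytest.raises(ValueError):
        central_tendency(Mixture([0.0], [1.0], [0.0]))


def test_variability_matches_monte_carlo_sampling(rng):
    m = random_mixture(rng, K=6)
    n = 1_000_000
    comps = rng.choice(m.K, size=n, p=m.phi / m.phi.sum())
    draws = rng.normal(m.mu[comps], m.sigma[comps])
    assert variability(m) == pytest.approx(draws.var(), rel=0.01)
    assert variability(m) >= min(m.sigma) ** 2


@given(mu1=st.floats(-50, 50), mu2=st.floats(-50, 50),
       s1=st.floats(0.1, 20), s2=st.floats(0.1, 20),
       p1=st.floats(0.05, 0.95))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_cue_weight_two_components_closed_form(mu1, mu2, s1, s2, p1):
    """The pairwise metric reduces to the two-category closed form."""
    m = Mixture([mu1, mu2], [s1, s2], [p1, 1.0 - p1])
    expected = p1 * (1 - p1) * (mu1 - mu2) ** 2 / (s1 * s2)
    # the O(K) evaluation cancels terms of size ~ mu^2/(s1 s2); allow the
    # corresponding float64 round-off when the closed form is ~0
    scale = 1.0 + (mu1 ** 2 + mu2 ** 2) / (s1 * s2)
    assert cue_weight(m) == pytest.approx(expected, rel=1e-9, abs=1e-12 * scale)


def test_cue_weight_examples_and_pairwise_oracle(rng):
    assert cue_weight(Mixture([2.0] * 4, [1.0] * 4, [0.25] * 4)) == 0.0
    m = Mixture([0.0, 1.0], [1.0, 1.0], [0.5, 0.5])
    assert cue_weight(m) == pytest.approx(0.25)
    for _ in range(20):
        m = random_mixture(rng, K=12)
        assert cue_weight(m) == pytest.approx(cue_weight_pairwise(m),
                                              rel=1e-9, abs=1e-12)


def test_gradient_deltas_match_finite_differences(rng):
    """Deltas are the rate-scaled gradient of the token log-likelihood."""
    rates = LearningRates(1.0, 1.0, 1.0)
    eps = 1e-6
    for _ in range(100):
        m = random_mixture(rng, K=4)
        x = float(rng.normal(0, 5))
        dphi, dmu, dsigma = gradient_deltas(x, m, rates)
        for j in range(m.K):
            for arr, delta in (("phi", dphi), ("mu", dmu), ("sigma", dsigma)):
                hi, lo = m.copy(), m.copy()
                getattr(hi, arr)[j] += eps
                getattr(lo, arr)[j] -= eps
                fd = (np.log(mixture_likelihood(x, hi))
                      - np.log(mixture_likelihood(x, lo))) / (2 * eps)
                assert delta[j] == pytest.approx(fd, rel=1e-5, abs=1e-7), \
                    f"{arr}[{j}] gradient mismatch"


def test_gradient_deltas_stationary_and_symmetric_cases():
    rates = LearningRates(0.5, 0.25, 1.0)
    single = Mixture([2.0], [1.5], [1.0])
    dphi, dmu, dsigma = gradient_deltas(2.0, single, rates)
    assert dmu[0] == 0.0
    assert dsigma[0] == pytest.approx(-0.25 / 1.5)
    sym = Mixture([-1.0, 1.0], [1.0, 1.0], [0.5, 0.5])
    _, dmu, _ = gradient_deltas(0.0, sym, rates)
    assert dmu[0] == pytest.approx(-dmu[1])
    assert dmu[0] > 0


def test_winner_take_all_updates_and_invariants(rng):
    rates = LearningRates(0.01, 0.01, 0.01)
    single = Mixture([0.0], [1.0], [1.0])
    apply_winner_take_all(single, gradient_deltas(0.3, single, rates))
    assert single.phi[0] == 1.0  # renormalization keeps a lone phi at exactly 1
    m = random_mixture(rng, K=6)
    before = m.phi.copy()
    deltas = gradient_deltas(0.5, m, rates)
    winner = int(np.argmax(deltas[0] * np.maximum(m.phi, m.phi_floor)))
    apply_winner_take_all(m, deltas)
    assert m.phi.sum() == pytest.approx(1.0, abs=1e-9)
    assert m.phi[winner] > before[winner]
    others = np.arange(m.K) != winner
    assert np.all(m.phi[others] < before[others])
    assert np.all(m.sigma >= m.sigma_floor)


@pytest.mark.parametrize("rule,expect_pruned", [("posterior", True),
                                                ("dphi", False)])
def test_long_run_competition_prunes_only_under_posterior_rule(rule, expect_pruned):
    """Posterior-based competition prunes a K=20 mixture trained on a
    two-Gaussian source down to ~2 surviving components; the phi-gradient
    rule keeps many components alive (no rich-get-richer dynamic)."""
    rng = np.random.default_rng(5)
    K = 20
    m = Mixture(rng.normal(0, 6, K), np.full(K, 2.0), np.full(K, 1 / K))
    rates = LearningRates(0.05, 0.04, 0.002)
    src_mu = np.array([-5.0, 5.0])
    for _ in range(60_000):
        x = rng.normal(src_mu[rng.integers(2)], 1.0)
        apply_winner_take_all(m, gradient_deltas(x, m, rates), rule)
    assert m.phi.sum() == pytest.approx(1.0, abs=1e-9)
    survivors = np.flatnonzero(m.phi > 1 / K)
    if expect_pruned:
        assert len(survivors) <= 3
        # parameter recovery: surviving means within 0.5 source-SD of truth
        big = survivors[np.argsort(m.phi[survivors])[-2:]]
        recovered = np.sort(m.mu[big])
        assert np.all(np.abs(recovered - src_mu) < 0.5)
    else:
        assert len(survivors) >= 5
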