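"""EM optimizer tests: monotonicity, acceleration, restarts, bootstrap."""

import numpy as np
import pytest

from glrelate.core import DegenerateSiteError, pair_loglikelihood, site_emissions
from glrelate.inference import (
    EmOptions,
    bootstrap_ci,
    em_step,
    estimate_pair,
    simplex_em,
    squarem_update,
)
from glrelate.pedsim import SimParams, simulate_scenario


def _random_instance(rng, n_sites=50):
    e = rng.uniform(0.05, 1.0, size=(n_sites, 9))
    j = rng.dirichlet(np.ones(9))
    return j, e


def test_em_monotonicity_many_random_instances(rng):
    """The log-likelihood never decreases under a plain EM step."""
    for _ in range(1000):
        j, e = _random_instance(rng, n_sites=30)
        j_new = em_step(j, e)
        assert abs(j_new.sum() - 1.0) < 1e-12 and j_new.min() >= 0
        assert pair_loglikelihood(j_new, e) >= pair_loglikelihood(j, e) - 1e-10


def test_uninformative_emissions_leave_j_unchanged(rng):
    """Constant emission rows make the posterior equal the prior."""
    e = np.outer(rng.uniform(0.5, 2.0, size=20), np.ones(9))
    j = rng.dirichlet(np.ones(9))
    np.testing.assert_allclose(em_step(j, e), j, atol=1e-12)


def test_single_site_em_is_normalized_product(rng):
    j, e = _random_instance(rng, n_sites=1)
    expected = j * e[0] / (j * e[0]).sum()
    np.testing.assert_allclose(em_step(j, e), expected, atol=1e-12)


def test_em_step_flags_degenerate_site():
    e = np.ones((4, 9))
    e[2] = 0.0
    with pytest.raises(DegenerateSiteError) as err:
        em_step(np.full(9, 1 / 9), e)
    assert err.value.site_index == 2


def test_squarem_returns_fixed_point(rng):
    """At an EM fixed point the accelerated update stays put."""
    e = np.outer(rng.uniform(0.5, 2.0, size=15), np.ones(9))  # any j is a fixed point
    j = rng.dirichlet(np.ones(9))
    np.testing.assert_allclose(squarem_update(j, e), j, atol=1e-10)


def test_squarem_never_decreases_loglik(rng):
    for _ in range(200):
        j, e = _random_instance(rng)
        j_new = squarem_update(j, e)
        assert abs(j_new.sum() - 1.0) < 1e-9
        assert pair_loglikelihood(j_new, e) >= pair_loglikelihood(j, e) - 1e-10


def test_accelerated_and_plain_em_find_same_optimum(rng):
    """SQUAREM and plain EM agree coefficient-wise on 50 random datasets.

    The plain-EM reference is iterated to a parameter-change criterion
    (max |dJ| < 1e-11) because near-flat likelihood directions let a
    log-likelihood stopping rule halt with residual parameter error.
    """
    for _ in range(50):
        j0, e = _random_instance(rng, n_sites=1500)
        j_fast, ll_fast, _, conv_fast = simplex_em(j0, e, tol=1e-12, max_iter=200_000)
        assert conv_fast
        j = j0.copy()
        for _step in range(500_000):
            j_next = em_step(j, e)
            done = np.abs(j_next - j).max() < 1e-11
            j = j_next
            if done:
                break
        assert done
        assert ll_fast == pytest.approx(pair_loglikelihood(j, e), abs=1e-6)
        np.testing.assert_allclose(j_fast, j, atol=1e-6)


def test_acceleration_reduces_iteration_count():
    """SQUAREM needs fewer EM-step evaluations than plain EM (median of 20)."""
    fast, slow = [], []
    for seed in range(20):
        gls, freqs, pair, _ = simulate_scenario(
            2, SimParams(n_sites=1_500, depth=4, error=0.001, maf=0.1, seed=100 + seed)
        )
        e = site_emissions(gls[pair[0]], gls[pair[1]], freqs)
        j0 = np.full(9, 1 / 9)
        _, _, n_fast, _ = simplex_em(j0, e, tol=1e-9, max_iter=50_000)
        _, _, n_slow, _ = simplex_em(j0, e, tol=1e-9, max_iter=50_000, use_acceleration=False)
        fast.append(n_fast)
        slow.append(n_slow)
    assert np.median(fast) < np.median(slow)


def test_estimate_is_deterministic_given_seed(cousin_dataset):
    opts = EmOptions(seed=42, n_restarts=2)
    r1 = estimate_pair(cousin_dataset["emissions"], opts)
    r2 = estimate_pair(cousin_dataset["emissions"], opts)
    np.testing.assert_array_equal(r1.j_hat, r2.j_hat)
    assert r1.loglik == r2.loglik and r1.n_iter == r2.n_iter


def test_estimate_recovers_cousin_coefficients(cousin_dataset):
    """Scenario-1 data: (J7, J8, J9) near (0, 0.25, 0.75), inbreeding terms near 0."""
    est = estimate_pair(cousin_dataset["emissions"], EmOptions(seed=5, n_restarts=2))
    assert est.converged
    assert est.j_hat[7] == pytest.approx(0.25, abs=0.06)
    assert est.j_hat[8] == pytest.approx(0.75, abs=0.06)
    assert est.j_hat[:7].sum() < 0.06


def test_estimate_loglik_matches_reported_vector(cousin_dataset):
    est = estimate_pair(cousin_dataset["emissions"], EmOptions(seed=5, n_restarts=2))
    assert est.loglik == pytest.approx(
        pair_loglikelihood(est.j_hat, cousin_dataset["emissions"]), abs=1e-6
    )


def test_boundary_examination_produces_exact_zeros(cousin_dataset):
    """Coefficients pinned near zero are clamped to exactly zero when harmless."""
    est = estimate_pair(cousin_dataset["emissions"], EmOptions(seed=5, n_restarts=2))
    assert (est.j_hat == 0.0).any()
    assert est.boundary_flags[est.j_hat == 0.0].all()
    assert est.j_hat.sum() == pytest.approx(1.0, abs=1e-10)


def test_unrelated_pair_estimate_tends_to_j9():
    """Two founders: the no-IBD coefficient dominates at large L."""
    from glrelate.pedsim import Pedigree, gene_drop, sample_frequencies, simulate_gls

    ped = Pedigree([("X", None, None), ("Y", None, None)])
    freqs = sample_frequencies(100_000, 0.1, seed=3)
    genomes = gene_drop(ped, freqs, seed=4)
    gls = simulate_gls(genomes, SimParams(n_sites=100_000, depth=8, seed=5))
    e = site_emissions(gls["X"], gls["Y"], freqs)
    est = estimate_pair(e, EmOptions(seed=6, n_restarts=2))
    assert est.j_hat[8] > 0.95


def test_estimate_chunk_invariance(cousin_dataset):
    """Site chunking (parallel-read order) cannot change the estimate."""
    e = cousin_dataset["emissions"]
    chunks = np.array_split(e, 7)
    e_rebuilt = np.concatenate(chunks)
    opts = EmOptions(seed=9, n_restarts=2)
    r1 = estimate_pair(e, opts)
    r2 = estimate_pair(e_rebuilt, opts)
    np.testing.assert_array_equal(r1.j_hat, r2.j_hat)


def test_estimate_rejects_empty_input():
    with pytest.raises(ValueError):
        estimate_pair(np.empty((0, 9)))


def test_nonconvergence_is_flagged(cousin_dataset):
    est = estimate_pair(cousin_dataset["emissions"],
                        EmOptions(seed=1, n_restarts=1, max_iter=4))
    assert not est.converged


def test_bootstrap_identical_sites_zero_width(rng):
    """Resampling identical sites reproduces the estimate: zero-width CIs."""
    gl_a = np.tile(np.array([1.0, 0.2, 0.01]), (60, 1))
    gl_b = np.tile(np.array([0.05, 1.0, 0.3]), (60, 1))
    freqs = np.full(60, 0.4)
    res = bootstrap_ci(gl_a, gl_b, freqs, n_boot=10, level=0.9,
                       opts=EmOptions(seed=2, n_restarts=2))
    for name in res.point:
        assert res.lower[name] == pytest.approx(res.upper[name], abs=1e-9)


def test_bootstrap_single_replicate_degenerate_interval(rng):
    gl_a = rng.random((40, 3)) + 0.05
    gl_b = rng.random((40, 3)) + 0.05
    freqs = rng.uniform(0.2, 0.8, size=40)
    res = bootstrap_ci(gl_a, gl_b, freqs, n_boot=1, level=0.95,
                       opts=EmOptions(seed=7, n_restarts=1))
    for name in res.point:
        assert res.lower[name] == pytest.approx(res.upper[name], abs=1e-12)


def test_bootstrap_deterministic_and_ordered(rng):
    gl_a = rng.random((50, 3)) + 0.05
    gl_b = rng.random((50, 3)) + 0.05
    freqs = rng.uniform(0.2, 0.8, size=50)
    opts = EmOptions(seed=11, n_restarts=1)
    r1 = bootstrap_ci(gl_a, gl_b, freqs, n_boot=8, level=0.9, opts=opts)
    r2 = bootstrap_ci(gl_a, gl_b, freqs, n_boot=8, level=0.9, opts=opts)
    assert r1.lower == r2.lower and r1.upper == r2.upper
    for name in r1.point:
        assert r1.lower[name] <= r1.upper[name]


def test_options_validation():
    with pytest.raises(ValueError):
        EmOptions(tol=0.0)
    with pytest.raises(ValueError):
        EmOptions(n_restarts=0)
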