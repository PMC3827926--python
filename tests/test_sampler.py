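import math

import numpy as np
import pytest
from scipy.special import expit

import profreg as pr
from profreg.model_core import MISSING, student_t_logpdf
from profreg.sampler import (
    impute_missing,
    initial_state,
    label_switch_moves,
    phi_posterior_params,
    stick_posterior_params,
    update_slice_and_allocations,
    update_theta,
)


def _theta_posterior_mean_oracle(k, n, priors=None, lo=-8.0, hi=8.0):
    """Dense-grid quadrature for the posterior mean of a single component's
    log odds given k cases among n members and the Student-t prior."""
    priors = priors or pr.PriorSpec()
    th = np.linspace(lo, hi, 40001)
    logf = (
        k * np.log(expit(th))
        + (n - k) * np.log(expit(-th))
        + student_t_logpdf(th, priors.theta_df, priors.theta_loc, priors.theta_scale)
    )
    f = np.exp(logf - logf.max())
    return float(np.trapezoid(th * f, th) / np.trapezoid(f, th))


# ---------------------------------------------------------------------------
# conjugate-update parameter arithmetic
# ---------------------------------------------------------------------------

def test_stick_posterior_params():
    a, b = stick_posterior_params(np.array([2, 1]), alpha=1.0)
    np.testing.assert_allclose(a, [3.0, 2.0])
    np.testing.assert_allclose(b, [2.0, 1.0])
    a, b = stick_posterior_params(np.zeros(3), alpha=2.5)   # no data -> prior
    np.testing.assert_allclose(a, [1, 1, 1])
    np.testing.assert_allclose(b, [2.5, 2.5, 2.5])
    N = 40
    a, b = stick_posterior_params(np.array([N, 0]), alpha=1.0)
    np.testing.assert_allclose(a, [1 + N, 1.0])
    np.testing.assert_allclose(b, [1.0, 1.0])


def test_phi_posterior_params():
    Z = np.array([0, 0, 0, 0, 0, 1])
    x = np.array([[0], [0], [0], [0], [0], [2]])
    posts = phi_posterior_params(Z, x, n_components=3, cardinalities=(3,), a_list=[np.ones(3)])
    np.testing.assert_allclose(posts[0][0], [6, 1, 1])   # counts (5,0,0) + ones
    np.testing.assert_allclose(posts[0][1], [1, 1, 2])
    np.testing.assert_allclose(posts[0][2], [1, 1, 1])   # empty -> prior


def test_phi_update_posterior_mean_matches_dirichlet_moment(small_truth):
    """Repeated conjugate updates on fixed allocations reproduce the
    Dirichlet posterior mean (a + counts) / sum."""
    data, labels = pr.generate_population(small_truth, 120, seed=2)
    data.x[data.x == MISSING] = 0  # avoid imputation effects here
    rng = np.random.default_rng(4)
    priors = pr.PriorSpec()
    state = initial_state(data, priors, rng)
    state.Z = labels % state.n_components
    state.imputed_x = data.x.copy()
    draws = []
    for _ in range(3000):
        pr_state = pr.sampler.update_phi(state, data, priors, rng)
        draws.append(pr_state.phi[0, 0, :5].copy())
    emp = np.mean(draws, axis=0)
    counts = np.bincount(data.x[state.Z == 0, 0], minlength=5)
    total = counts.sum() + 5.0
    expected = (1.0 + counts) / total
    se = np.sqrt(expected * (1 - expected) / (total + 1) / len(draws))
    np.testing.assert_allclose(emp, expected, atol=4 * se.max() + 1e-3)


# ---------------------------------------------------------------------------
# Metropolis theta update against a 1-D quadrature oracle
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k, n, check", [
    (10, 10, "gt1"),        # all cases: posterior well above 1
    (5, 10, "near0"),       # balanced: centred near 0
    (47, 500, "oracle"),    # rare outcome: match quadrature closely
])
def test_update_theta_matches_quadrature(k, n, check):
    y = np.r_[np.ones(k), np.zeros(n - k)].astype(int)
    data_y = y if 0 < k < n else np.r_[y, [1 - y[-1]]]  # Dataset needs both classes
    x = np.zeros((len(data_y), 1), dtype=int)
    data = pr.Dataset(data_y, x, [2])
    priors = pr.PriorSpec()
    rng = np.random.default_rng(8)
    state = initial_state(data, priors, rng)
    state.Z[:] = 0
    state.Z[n:] = 1  # park any padding subject in another component
    draws = []
    for t in range(25000):
        update_theta(state, data, priors, rng, proposal_sd=0.6)
        if t > 1000:
            draws.append(state.theta[0])
    draws = np.asarray(draws)
    m = float(draws.mean())
    nb = 40
    bs = len(draws) // nb
    batches = draws[: nb * bs].reshape(nb, bs).mean(axis=1)
    se = batches.std(ddof=1) / math.sqrt(nb)
    oracle = _theta_posterior_mean_oracle(k, n)
    if check == "gt1":
        assert m > 1.0 and oracle > 1.0
    elif check == "near0":
        assert abs(m) < 0.25 and abs(oracle) < 0.05
    np.testing.assert_allclose(m, oracle, atol=4 * se + 0.02)


def test_update_theta_empty_component_samples_prior():
    data = pr.Dataset([1, 0], np.zeros((2, 1), dtype=int), [2])
    priors = pr.PriorSpec()
    rng = np.random.default_rng(3)
    state = initial_state(data, priors, rng)
    state.Z[:] = 0  # component 1 empty
    draws = [update_theta(state, data, priors, rng).theta[1] for _ in range(8000)]
    from scipy.stats import kstest, t as sp_t

    stat = kstest(draws, sp_t(df=7, loc=0, scale=2.5).cdf)
    assert stat.pvalue > 0.01


# ---------------------------------------------------------------------------
# beta update
# ---------------------------------------------------------------------------

def test_update_beta_recovers_strong_confounder_effect():
    rng = np.random.default_rng(12)
    N = 1500
    w = (rng.random(N) < 0.5).astype(float)[:, None]
    eta = -0.5 + 2.0 * w[:, 0]
    y = (rng.random(N) < expit(eta)).astype(int)
    x = np.zeros((N, 1), dtype=int)
    data = pr.Dataset(y, x, [2], w=w)
    chain = pr.run_chain(
        data, pr.PriorSpec(), pr.SamplerControls(n_sweeps=1500, n_burnin=500, thin=2, seed=13)
    )
    bmean, bsd = chain.beta[:, 0].mean(), chain.beta[:, 0].std(ddof=1)
    assert abs(bmean - 2.0) < 2 * max(bsd, 0.15)


def test_update_beta_without_fixed_effects_is_noop():
    data = pr.Dataset([1, 0], np.zeros((2, 1), dtype=int), [2])
    rng = np.random.default_rng(0)
    state = initial_state(data, pr.PriorSpec(), rng)
    before = state.beta.copy()
    pr.sampler.update_beta(state, data, pr.PriorSpec(), rng)
    np.testing.assert_array_equal(state.beta, before)


# ---------------------------------------------------------------------------
# missing-value imputation
# ---------------------------------------------------------------------------

def test_impute_missing_frequencies():
    y = np.array([1, 0])
    x = np.full((2, 1), MISSING)
    data = pr.Dataset(y, x, [2])
    rng = np.random.default_rng(21)
    priors = pr.PriorSpec()
    state = initial_state(data, priors, rng)
    state.Z[:] = 0
    state.phi[0, 0, :2] = [0.2, 0.8]
    draws = []
    for _ in range(20000):
        impute_missing(state, data, priors, rng)
        draws.append(state.imputed_x[0, 0])
    freq = np.mean(draws)
    assert freq == pytest.approx(0.8, abs=3 * math.sqrt(0.16 / 20000) + 1e-9)
    # degenerate phi pins the imputation
    state.phi[0, 0, :2] = [1.0, 0.0]
    impute_missing(state, data, priors, rng)
    assert state.imputed_x[0, 0] == 0


# ---------------------------------------------------------------------------
# slice allocations
# ---------------------------------------------------------------------------

def test_allocation_follows_dominant_component():
    data = pr.Dataset([1, 0], np.zeros((2, 1), dtype=int), [2])
    priors = pr.PriorSpec()
    rng = np.random.default_rng(5)
    state = initial_state(data, priors, rng)
    hits = 0
    n_iter = 4000
    for _ in range(n_iter):
        # make component 0 dominant and all components identical in
        # likelihood (updates may have extended the representation)
        state.V = np.array([0.999, 0.5])
        state.psi = pr.stick_weights(state.V)
        state.theta = np.zeros(2)
        state.phi = np.full((2, 1, 2), 0.5)
        state.Z = np.minimum(state.Z, 1)
        update_slice_and_allocations(state, data, priors, rng)
        hits += state.Z[0] == 0
    assert hits / n_iter >= 0.995


def test_allocation_marginal_proportional_to_psi_for_identical_components():
    """With identical component parameters the stationary allocation law of
    the slice chain is proportional to the stick weights."""
    data = pr.Dataset([1, 0], np.array([[0], [1]]), [2])
    priors = pr.PriorSpec(alpha=0.5)
    rng = np.random.default_rng(17)
    state = initial_state(data, priors, rng)
    psi_target = pr.stick_weights([0.6, 0.75])   # (0.6, 0.3)
    counts = np.zeros(3)
    n_iter = 30000
    for _ in range(n_iter):
        state.V = np.array([0.6, 0.75])
        state.psi = psi_target.copy()
        state.theta = np.zeros(2)
        state.phi = np.full((2, 1, 2), 0.5)
        state.Z = np.minimum(state.Z, 1)
        update_slice_and_allocations(state, data, priors, rng)
        counts[min(state.Z[0], 2)] += 1
    ratio = counts[0] / counts[1]
    se = ratio * math.sqrt(1 / counts[0] + 1 / counts[1])
    assert ratio == pytest.approx(0.6 / 0.3, abs=4 * se)


def test_slice_extension_cap_raises():
    data = pr.Dataset([1, 0], np.zeros((2, 1), dtype=int), [2])
    priors = pr.PriorSpec(alpha=50.0)
    rng = np.random.default_rng(2)
    state = initial_state(data, priors, rng)
    state.u[:] = 1e-200  # absurd slice level forces endless extension
    with pytest.raises(RuntimeError, match="stick extensions"):
        # patch u draw so the tiny level persists
        class FixedU:
            def __getattr__(self, name):
                return getattr(rng, name)

            def uniform(self, lo, hi):
                return np.full_like(np.atleast_1d(hi), 1e-200)

        update_slice_and_allocations(state, data, priors, FixedU(), max_extensions=200)


# ---------------------------------------------------------------------------
# label-switch moves
# ---------------------------------------------------------------------------

def test_label_moves_preserve_joint_loglik(small_truth):
    data, _ = pr.generate_population(small_truth, 50, seed=6)
    priors = pr.PriorSpec()
    rng = np.random.default_rng(7)
    state = initial_state(data, priors, rng)
    before = pr.joint_loglik(state, data, priors)
    for _ in range(50):
        label_switch_moves(state, rng, n_moves=2)
        assert pr.joint_loglik(state, data, priors) == pytest.approx(before, rel=1e-10)


def test_label_swap_of_empty_components_always_accepts():
    data = pr.Dataset([1, 0], np.zeros((2, 1), dtype=int), [2])
    rng = np.random.default_rng(1)
    state = initial_state(data, pr.PriorSpec(), rng)
    state.Z[:] = 0
    state.V = np.array([0.5, 0.2, 0.3, 0.4])
    state.psi = pr.stick_weights(state.V)
    state.theta = np.array([0.0, 1.0, 2.0, 3.0])
    state.phi = np.broadcast_to(np.full((1, 1, 2), 0.5), (4, 1, 2)).copy()
    state.accept_counts = {k: 0 for k in ("label_accept", "label_prop")}

    class PickEmpties:
        def __getattr__(self, name):
            return getattr(rng, name)

        def choice(self, n, size, replace):
            return np.array([1, 3])  # both empty

    for _ in range(20):
        label_switch_moves(state, PickEmpties(), n_moves=1)
    assert state.accept_counts["label_accept"] == 20


# ---------------------------------------------------------------------------
# run_chain contracts
# ---------------------------------------------------------------------------

def test_run_chain_deterministic_given_seed(small_truth):
    data, _ = pr.generate_population(small_truth, 100, seed=9)
    controls = pr.SamplerControls(n_sweeps=200, n_burnin=50, thin=3, seed=99)
    c1 = pr.run_chain(data, pr.PriorSpec(), controls)
    c2 = pr.run_chain(data, pr.PriorSpec(), controls)
    np.testing.assert_array_equal(c1.Z, c2.Z)
    np.testing.assert_array_equal(c1.loglik, c2.loglik)
    for t in range(c1.n_retained):
        np.testing.assert_array_equal(c1.theta[t], c2.theta[t])
        np.testing.assert_array_equal(c1.phi[t], c2.phi[t])


def test_run_chain_retention_and_state_invariants(small_fit):
    chain = small_fit["chain"]
    ctl = chain.controls
    assert chain.n_retained == (ctl.n_sweeps - ctl.n_burnin) // ctl.thin
    for t in range(chain.n_retained):
        K = np.unique(chain.Z[t]).size
        assert chain.K[t] == K
        assert chain.theta[t].shape[0] == K          # stored components are occupied
        psi = chain.psi[t]
        assert ((psi > 0) & (psi < 1)).all() and psi.sum() < 1.0
        for j, L in enumerate(chain.cardinalities):
            rows = chain.phi[t][:, j, :L]
            np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-10)
            assert (rows >= 0).all()
    assert np.isfinite(chain.loglik).all()


def test_run_chain_loglik_trace_has_no_drift(small_fit):
    """Detailed-balance smoke test: first and second halves of the retained
    joint-log-likelihood trace agree within Monte-Carlo error."""
    ll = small_fit["chain"].loglik
    half = len(ll) // 2
    a, b = ll[:half], ll[half:]
    se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    assert abs(a.mean() - b.mean()) < 5 * se


def test_prior_only_pairwise_coclustering_matches_crp():
    data = pr.Dataset([1, 0], np.zeros((2, 1), dtype=int), [2])
    for alpha in (1.0, 3.6):
        chain = pr.run_chain(
            data, pr.PriorSpec(alpha=alpha),
            pr.SamplerControls(n_sweeps=21000, n_burnin=1000, thin=1, seed=31),
            prior_only=True,
        )
        same = (chain.Z[:, 0] == chain.Z[:, 1]).astype(float)
        nb = 40
        bs = len(same) // nb
        batches = same[: nb * bs].reshape(nb, bs).mean(axis=1)
        se = batches.std(ddof=1) / math.sqrt(nb)
        assert batches.mean() == pytest.approx(1 / (1 + alpha), abs=3.5 * se)


def test_chain_roundtrips_through_directory(tmp_path, small_fit):
    chain = small_fit["chain"]
    d = chain.save(tmp_path / "chain")
    again = pr.ChainOutput.load(d)
    np.testing.assert_array_equal(chain.Z, again.Z)
    np.testing.assert_allclose(chain.beta, again.beta)
    np.testing.assert_array_equal(chain.K, again.K)
    assert again.cardinalities == chain.cardinalities
    for t in range(chain.n_retained):
        np.testing.assert_allclose(chain.psi[t], again.psi[t])
        np.testing.assert_allclose(chain.theta[t], again.theta[t])
        np.testing.assert_allclose(chain.phi[t], again.phi[t])
    assert again.controls == chain.controls


def test_controls_validation():
    with pytest.raises(ValueError):
        pr.SamplerControls(n_sweeps=100, n_burnin=100, seed=1)
    with pytest.raises(ValueError):
        pr.SamplerControls(thin=0, seed=1)
    with pytest.raises(ValueError):
        pr.SamplerControls(proposal_sd_theta=-1, seed=1)
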