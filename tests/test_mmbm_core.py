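"""Tests of the multinomial-logit machinery, gradients and the sampler."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mmbm
from mmbm.data_model import CATEGORIES, NONREFERENCE_CATEGORIES
from mmbm.mmbm_core import (
    ModelSpec,
    PriorConfig,
    SamplerConfig,
    _corr_chol_terms,
    _PosteriorDensity,
    category_probabilities,
    event_log_likelihood,
    linear_predictors,
    noncentred_effects,
)

K = len(NONREFERENCE_CATEGORIES)


# --------------------------------------------------------------------------
# linear predictors
# --------------------------------------------------------------------------


def test_linear_predictors_all_zero():
    eta = linear_predictors([], np.zeros(K))
    np.testing.assert_array_equal(eta, np.zeros(K))


def test_linear_predictors_intercepts_only():
    alpha = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    np.testing.assert_array_equal(linear_predictors([], alpha), alpha)


def test_linear_predictors_matches_dot_product_oracle(rng):
    x = rng.standard_normal(7)
    alpha = rng.standard_normal(K)
    beta = rng.standard_normal((7, K))
    u1, u2 = rng.standard_normal((2, K))
    eta = linear_predictors(x, alpha, beta, [u1, u2])
    oracle = np.array(
        [
            alpha[k] + sum(x[p] * beta[p, k] for p in range(7)) + u1[k] + u2[k]
            for k in range(K)
        ]
    )
    np.testing.assert_allclose(eta, oracle, atol=1e-12)


def test_linear_predictors_dimension_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        linear_predictors(np.ones(3), np.zeros(K), np.zeros((7, K)))


# --------------------------------------------------------------------------
# category probabilities
# --------------------------------------------------------------------------


def test_uniform_probabilities_at_zero():
    np.testing.assert_allclose(category_probabilities(np.zeros(K)), np.full(6, 1 / 6))


def test_analytic_probability_log2():
    p = category_probabilities(np.array([np.log(2), 0, 0, 0, 0]))
    assert p[0] == pytest.approx(1 / 7)  # reference
    assert p[1] == pytest.approx(2 / 7)


def test_probabilities_stable_at_extreme_eta():
    eta = np.array([700.0, -700.0, 0.0, 1.0, -1.0])
    p = category_probabilities(eta)
    assert np.all(np.isfinite(p))
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert p[1] == pytest.approx(1.0)  # the +700 category takes all mass


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(-30, 30), min_size=K, max_size=K))
def test_probabilities_sum_to_one_and_permutation_equivariant(eta):
    eta = np.array(eta)
    p = category_probabilities(eta)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    perm = np.array([2, 0, 4, 1, 3])
    p_perm = category_probabilities(eta[perm])
    np.testing.assert_allclose(p_perm[1:], p[1:][perm], atol=1e-12)
    assert p_perm[0] == pytest.approx(p[0], abs=1e-12)


# --------------------------------------------------------------------------
# noncentred effects
# --------------------------------------------------------------------------


def test_noncentred_zero_and_identity():
    sigma = np.ones(K)
    L = np.eye(K)
    np.testing.assert_array_equal(
        noncentred_effects(np.zeros((3, K)), sigma, L), np.zeros((3, K))
    )
    z = np.arange(15.0).reshape(3, K)
    np.testing.assert_array_equal(noncentred_effects(z, sigma, L), z)


def test_noncentred_rejects_bad_cholesky():
    with pytest.raises(ValueError, match="triangular"):
        noncentred_effects(np.zeros((1, K)), np.ones(K), np.full((K, K), 0.5))
    bad = np.eye(K)
    bad[2, 2] = -1.0
    with pytest.raises(ValueError, match="positive"):
        noncentred_effects(np.zeros((1, K)), np.ones(K), bad)


def test_noncentred_covariance_matches_target(rng):
    """Empirical covariance of 1e5 transformed draws equals
    diag(sigma) L L' diag(sigma) within 5%."""
    z = rng.standard_normal(10)
    L, _ = _corr_chol_terms(z, K, 2.0)
    sigma = np.array([0.4, 0.3, 0.8, 0.9, 0.5])
    target = (sigma[:, None] * (L @ L.T)) * sigma[None, :]
    zeta = rng.standard_normal((100_000, K))
    u = noncentred_effects(zeta, sigma, L)
    emp = np.cov(u.T)
    np.testing.assert_allclose(emp, target, rtol=0.05, atol=0.01)


def test_corr_transform_fast_path_matches_reference(rng):
    """The compiled correlation transform agrees with the numpy reference."""
    from mmbm import mmbm_core

    z = rng.standard_normal(10)
    L, f, df_dz, J = mmbm_core._corr_transform_with_grads(z, K, 2.0)
    Z = z[None, :] + 1j * mmbm_core._CS_H * np.eye(10)
    L_ref, f_ref = mmbm_core._corr_chol_terms(Z, K, 2.0)
    np.testing.assert_allclose(L, L_ref[0].real, atol=1e-14)
    assert f == pytest.approx(float(f_ref[0].real), abs=1e-12)
    np.testing.assert_allclose(df_dz, f_ref.imag / mmbm_core._CS_H, atol=1e-12)
    np.testing.assert_allclose(J, L_ref.imag / mmbm_core._CS_H, atol=1e-12)


def test_corr_transform_yields_valid_correlation(rng):
    for _ in range(20):
        z = 2.0 * rng.standard_normal(10)
        L, _ = _corr_chol_terms(z, K, 2.0)
        omega = L @ L.T
        np.testing.assert_allclose(np.diag(omega), 1.0, atol=1e-12)
        np.testing.assert_allclose(omega, omega.T, atol=1e-12)
        assert np.linalg.eigvalsh(omega).min() > -1e-12


# --------------------------------------------------------------------------
# log likelihood
# --------------------------------------------------------------------------


def test_loglik_all_zero_params_is_log_one_sixth():
    ll = event_log_likelihood(np.zeros((4, K)), np.array([0, 1, 3, 5]))
    np.testing.assert_allclose(ll, np.log(1 / 6), atol=1e-12)


def test_loglik_near_certain_reference():
    ll = event_log_likelihood(np.full((1, K), -50.0), np.array([0]))
    assert ll[0] == pytest.approx(0.0, abs=1e-12)


def test_loglik_matches_enumeration_oracle(rng):
    """20-event toy set vs direct softmax enumeration, to 1e-12."""
    eta = rng.standard_normal((20, K))
    cats = rng.integers(0, 6, size=20)
    ll = event_log_likelihood(eta, cats)
    for i in range(20):
        full = np.concatenate([[0.0], eta[i]])
        probs = np.exp(full) / np.exp(full).sum()
        assert ll[i] == pytest.approx(np.log(probs[cats[i]]), abs=1e-12)


def test_loglik_invariant_to_event_order(rng):
    eta = rng.standard_normal((20, K))
    cats = rng.integers(0, 6, size=20)
    perm = rng.permutation(20)
    ll = event_log_likelihood(eta, cats)
    ll_perm = event_log_likelihood(eta[perm], cats[perm])
    assert ll.sum() == pytest.approx(ll_perm.sum(), abs=1e-10)
    np.testing.assert_allclose(ll[perm], ll_perm, atol=1e-12)


def test_log_likelihood_api_with_unit_effects(rng):
    events = pd.DataFrame(
        {
            "individual_id": ["a", "a", "b"],
            "scan_id": ["s1", "s1", "s1"],
            "behaviour": ["rest", "work", "eat"],
        }
    )
    alpha = rng.standard_normal(K)
    u = {"a": rng.standard_normal(K), "b": rng.standard_normal(K)}
    ll = mmbm.log_likelihood(events, {"alpha": alpha, "u_individual": u})
    for i, (iid, beh) in enumerate(zip(events.individual_id, events.behaviour)):
        eta = alpha + u[iid]
        expected = event_log_likelihood(eta[None, :], [CATEGORIES.index(beh)])[0]
        assert ll[i] == pytest.approx(expected, abs=1e-12)


# --------------------------------------------------------------------------
# joint density gradient (regression test for the sampler's target)
# --------------------------------------------------------------------------


def test_posterior_gradient_matches_finite_differences(rng):
    R = 30
    Y = rng.multinomial(50, [1 / 6] * 6, size=R).astype(float)
    X = rng.standard_normal((R, 3))
    idx = {"individual": rng.integers(0, 8, R), "scan": np.arange(R)}
    d = _PosteriorDensity(
        Y, X, idx, PriorConfig(), correlated={"individual": True, "scan": False}
    )
    theta = 0.3 * rng.standard_normal(d.dim)
    _, g = d.logp_grad(theta)
    eps = 1e-6
    for i in rng.choice(d.dim, size=40, replace=False):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        fd = (d.logp_grad(tp)[0] - d.logp_grad(tm)[0]) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


# --------------------------------------------------------------------------
# fitting behaviour
# --------------------------------------------------------------------------


def _events_from_counts(counts_by_ind):
    """Build an events frame giving each individual fixed category counts."""
    rows = []
    for iid, counts in counts_by_ind.items():
        k = 0
        for cat, n in counts.items():
            for _ in range(n):
                k += 1
                rows.append(
                    {"individual_id": iid, "scan_id": f"{iid}_s1",
                     "event_index": k, "behaviour": cat}
                )
    return pd.DataFrame(rows)


def _covariates_for(individuals):
    table = pd.DataFrame(
        {
            "individual_id": list(individuals),
            "scan_id": [f"{i}_s1" for i in individuals],
            "sex": "F",
            "group_id": "g1",
            "litter_id": "l1",
        }
    )
    return table


def test_balanced_data_centres_intercepts_near_zero():
    """Exactly equal category counts, no covariates: intercept posteriors
    should straddle zero."""
    counts = {f"i{j}": {c: 30 for c in CATEGORIES} for j in range(12)}
    events = _events_from_counts(counts)
    cov = _covariates_for(counts.keys())
    spec = ModelSpec(variant="M1", sex="F",
                     sampler=SamplerConfig(chains=1, iterations=400, seed=2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mmbm.fit(spec, events, cov)
    a = res.stacked("alpha")
    assert np.all(np.abs(a.mean(0)) < 2 * a.std(0))


def test_sigma_concentrates_near_zero_without_re_variance(rng):
    """Data with no between-individual heterogeneity: posterior median of the
    individual-level SDs stays small."""
    p = np.full(6, 1 / 6)
    counts = {}
    for j in range(100):
        draw = rng.multinomial(200, p)
        counts[f"i{j:03d}"] = dict(zip(CATEGORIES, draw.tolist()))
    events = _events_from_counts(counts)
    cov = _covariates_for(counts.keys())
    spec = ModelSpec(variant="M1", sex="F",
                     sampler=SamplerConfig(chains=1, iterations=400, seed=3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mmbm.fit(spec, events, cov)
    med = np.median(res.stacked("sigma_individual"), axis=0)
    assert np.all(med < 0.3)


def test_prior_predictive_matches_analytic_priors(small_dataset):
    """With the likelihood switched off the sampler must reproduce the
    priors: KS tests against Normal(0,5) for intercepts and Exponential(1)
    for SDs."""
    spec = ModelSpec(variant="M1", sex="F",
                     sampler=SamplerConfig(chains=1, iterations=1100, warmup=100, seed=4))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mmbm.fit(spec, small_dataset.events, small_dataset.covariates,
                       likelihood_weight=0.0)
    alpha = res.stacked("alpha")
    sigma = res.stacked("sigma_individual")
    # thin to reduce autocorrelation before the KS comparison
    for k in range(K):
        a = alpha[::4, k]
        assert stats.kstest(a, stats.norm(0, 5).cdf).pvalue > 0.01
        s = sigma[::4, k]
        assert stats.kstest(s, stats.expon.cdf).pvalue > 0.01


def test_posterior_result_roundtrip(m1_fit, tmp_path):
    m1_fit.save(tmp_path / "post")
    back = mmbm.PosteriorResult.load(tmp_path / "post")
    np.testing.assert_allclose(back.draws["alpha"], m1_fit.draws["alpha"])
    np.testing.assert_allclose(back.log_lik, m1_fit.log_lik)
    assert back.spec.variant == "M1"
    assert back.rhat.keys() == m1_fit.rhat.keys()


def test_correlation_draws_are_valid_matrices(m1_fit):
    draws = m1_fit.stacked("corr_individual")
    np.testing.assert_allclose(
        draws.diagonal(axis1=1, axis2=2), 1.0, atol=1e-10
    )
    eig = np.linalg.eigvalsh(draws)
    assert eig.min() > -1e-10


def test_pointwise_loglik_nonpositive(m1_fit):
    assert np.all(m1_fit.log_lik <= 1e-12)


def test_seed_stability_of_correlation_means(small_dataset):
    """Two fits differing only in seed agree on correlation posterior means
    within Monte Carlo error."""
    import arviz as az

    results = []
    for seed in (31, 32):
        spec = ModelSpec(variant="M1", sex="F",
                         sampler=SamplerConfig(chains=2, iterations=800, seed=seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results.append(mmbm.fit(spec, small_dataset.events, small_dataset.covariates))
    iu = np.triu_indices(K, 1)
    for (i, j) in zip(*iu):
        a = results[0].draws["corr_individual"][:, :, i, j]
        b = results[1].draws["corr_individual"][:, :, i, j]
        mcse = []
        for d in (a, b):
            ess = float(np.asarray(az.ess(az.convert_to_dataset(d))["x"]).ravel()[0])
            mcse.append(d.std() / np.sqrt(max(ess, 4)))
        # 2 combined Monte Carlo SEs, floored for very short chains
        tol = max(2 * np.hypot(*mcse), 0.05)
        assert abs(a.mean() - b.mean()) < tol


def test_single_litter_warns(small_dataset):
    events = small_dataset.events
    cov = small_dataset.covariates
    table = cov.table.copy()
    table["litter_id"] = "only_one"
    spec = ModelSpec(variant="M3", sex="F", correlated_secondary_levels=False,
                     sampler=SamplerConfig(chains=1, iterations=60, warmup=40, seed=1))
    with pytest.warns(UserWarning, match="litter"):
        mmbm.fit(spec, events, mmbm.Covariates(table=table, scaling=cov.scaling,
                                               ranges=cov.ranges))
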