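"""CRTE/DCRTE estimators, standard errors and bias/MSE approximations."""

import math

import numpy as np
import pytest

from crte.datagen import ProcessSpec, generate
from crte.entropy_estimators import (
    EntropyConfig,
    UnstableTailError,
    crte_asymptotic_se,
    crte_estimate,
    crte_functional,
    dcrte_asymptotic_se,
    dcrte_estimate,
    dcrte_functional,
    entropy_bias_theory,
    mse_theory,
)
from crte.kernels_bandwidths import make_bandwidths
from crte.theory import (
    crte_exact,
    dcrte_exact,
    exponential_model,
    sigma_eta_sq_exact,
    uniform_model,
)

CK_GAUSS = 1.0 / (2.0 * math.sqrt(math.pi))
BETA_HALF = 4.0 / 3.0


@pytest.mark.parametrize("alpha", [0.6, 1.5, 2.0, 3.0])
@pytest.mark.parametrize("model_fn", [exponential_model, uniform_model])
def test_oracle_mode_matches_exact_values(alpha, model_fn):
    """With the exact survival injected, the estimation pipeline
    reproduces the closed-form entropies to integration tolerance."""
    model = model_fn(1.0)
    upper = 60.0 if model.name == "exponential" else 1.0
    got = crte_functional(model.sf, alpha, upper=upper, grid_points=4096)
    assert got == pytest.approx(crte_exact(model, alpha), abs=1e-6)


@pytest.mark.parametrize("t", [0.0, 0.5, 2.0])
def test_oracle_dcrte_memoryless(t):
    model = exponential_model(1.0)
    value, m, a = dcrte_functional(model.sf, 2.0, t, upper=t + 60.0,
                                   grid_points=4096)
    assert value == pytest.approx(0.5, abs=1e-6)
    assert value == pytest.approx((1.0 - m / a), abs=1e-12)


def test_oracle_dcrte_uniform():
    model = uniform_model(1.0)
    value, _, _ = dcrte_functional(model.sf, 2.0, 0.0, upper=1.0,
                                   grid_points=4096)
    assert value == pytest.approx(2.0 / 3.0, abs=1e-6)


def test_estimate_recovers_exponential_crte(exp_sample, gaussian):
    """Parameter recovery at n=5000: one seeded estimate lies within 3
    asymptotic standard errors of the true value 1/2."""
    n = 5000
    sample = exp_sample(n, seed=21)
    bw = make_bandwidths(1.0, 0.5, n)
    est = crte_estimate(sample, gaussian, bw, EntropyConfig(alpha=2.0))
    assert est.asymptotic_se is not None
    assert abs(est.value - 0.5) < 3.0 * est.asymptotic_se


def test_estimate_scale_change_of_variables(exp_sample, gaussian):
    """Scaling the data and c by a turns the integral I into a*I, so the
    estimate becomes (1/(alpha-1)) * (1 - a*I)."""
    a, n, alpha = 2.0, 200, 2.0
    sample = exp_sample(n)
    from crte.density_survival import Sample
    scaled = Sample(observations=sample.observations * a)
    bw1 = make_bandwidths(1.0, 0.5, n)
    bwa = make_bandwidths(a, 0.5, n)
    cfg = EntropyConfig(alpha=alpha, compute_se=False)
    v1 = crte_estimate(sample, gaussian, bw1, cfg).value
    va = crte_estimate(scaled, gaussian, bwa, cfg).value
    i1 = 1.0 - (alpha - 1.0) * v1
    assert va == pytest.approx((1.0 - a * i1) / (alpha - 1.0), abs=1e-6)


def test_dcrte_at_zero_age_close_to_crte(exp_sample, gaussian):
    """At t=0 the dynamic estimator differs from the static one only by
    the kernel mass leaking below zero (Ahat(0) ~ total_mass^alpha)."""
    n = 400
    sample = exp_sample(n, seed=33)
    bw = make_bandwidths(1.0, 0.5, n)
    crte = crte_estimate(sample, gaussian, bw,
                         EntropyConfig(alpha=2.0, compute_se=False))
    dcrte = dcrte_estimate(sample, gaussian, bw,
                           EntropyConfig(alpha=2.0, t=0.0, compute_se=False))
    # the sub-zero mass at n=400, b_1=1 is small but not negligible
    assert abs(dcrte.value - crte.value) < 0.1
    m_hat, a_hat = dcrte.components
    assert dcrte.value == pytest.approx(
        (1.0 - m_hat / a_hat), abs=1e-12)


def test_dcrte_unstable_tail_rejected(exp_sample, gaussian):
    sample = exp_sample(100)
    bw = make_bandwidths(1.0, 0.5, 100)
    far_t = float(sample.observations.max()) + 15.0
    with pytest.raises(UnstableTailError):
        dcrte_estimate(sample, gaussian, bw,
                       EntropyConfig(alpha=2.0, t=far_t, compute_se=False))


def test_alpha_validation_and_warning():
    with pytest.raises(ValueError):
        EntropyConfig(alpha=1.0)
    with pytest.raises(ValueError):
        EntropyConfig(alpha=-0.5)
    with pytest.warns(UserWarning, match="alpha"):
        EntropyConfig(alpha=0.4)


def test_se_refused_below_half(exp_sample, gaussian):
    with pytest.raises(ValueError):
        crte_asymptotic_se(exponential_model(1.0).sf, 0.4, 100, 0.1,
                           BETA_HALF, CK_GAUSS, upper=50.0)


def test_crte_se_closed_form_oracle():
    """Oracle-mode SE: sigma_eta^2 = 3/(8*sqrt(pi)) for Exponential(1),
    alpha=2, Gaussian kernel, theta=1/2; SE = sqrt(sigma^2/(n*b_n))."""
    model = exponential_model(1.0)
    n = 1000
    b_n = n ** -0.5
    se = crte_asymptotic_se(model.sf, 2.0, n, b_n, BETA_HALF, CK_GAUSS,
                            upper=60.0, grid_points=4096)
    sigma_sq = 3.0 / (8.0 * math.sqrt(math.pi))
    assert se == pytest.approx(math.sqrt(sigma_sq / (n * b_n)), rel=1e-6)


def test_se_shrinks_as_n_quarter_power():
    """Doubling n with theta=1/2 shrinks the SE by 2^(-1/4)."""
    model = exponential_model(1.0)
    ses = [crte_asymptotic_se(model.sf, 2.0, n, n ** -0.5, BETA_HALF,
                              CK_GAUSS, upper=60.0) for n in (1000, 2000)]
    assert ses[1] / ses[0] == pytest.approx(2.0 ** -0.25, rel=1e-9)


def test_dcrte_se_hand_substitution():
    """Exponential(1), alpha=2, t=1: closed-form tail integrals plugged
    into the dynamic variance; oracle = independent scalar arithmetic."""
    model = exponential_model(1.0)
    n, t, alpha = 1000, 1.0, 2.0
    b_n = n ** -0.5
    se = dcrte_asymptotic_se(model.sf, alpha, t, n, b_n, BETA_HALF,
                             CK_GAUSS, upper=60.0, grid_points=4096)
    sft = math.exp(-t)
    sigma_sq = (alpha ** 2 * CK_GAUSS
                * (math.exp(-3 * t) / 3 + (math.exp(-2 * t) / 2) ** 2 * sft)
                / ((alpha - 1) ** 2 * BETA_HALF ** 2 * sft ** 4))
    assert se == pytest.approx(math.sqrt(sigma_sq / (n * b_n)), rel=1e-5)


def test_bias_theory_flag_and_value(gaussian):
    """theta=1/2 flags the bias as not applicable (divergent beta_{2.5});
    theta=1/4 matches the analytic reduction for Exponential(1), alpha=2:
    integral int_0^inf e^(-x)*e^(-x) dx = 1/2."""
    model = exponential_model(1.0)
    assert entropy_bias_theory(model, 2.0, 100,
                               make_bandwidths(1.0, 0.5, 100), gaussian) is None
    n, theta, alpha = 100, 0.25, 2.0
    bw = make_bandwidths(1.0, theta, n)
    got = entropy_bias_theory(model, alpha, n, bw, gaussian)
    beta_half = 1.0 / (1.0 - theta / 2.0)
    beta_52 = 1.0 / (1.0 - 2.5 * theta)
    expected = -(alpha / (alpha - 1.0)) * bw.b_n ** 2 * gaussian.c2 \
        * beta_52 / (2.0 * beta_half) * 0.5
    assert got == pytest.approx(expected, rel=1e-6)


def test_mse_theory_reconstruction_and_monotone(gaussian):
    """MSE = bias^2 + sigma^2/(n*b_n), decreasing in n and -> 0."""
    model = exponential_model(1.0)
    vals = []
    for n in (100, 1000, 10_000):
        bw = make_bandwidths(1.0, 0.25, n)
        mse = mse_theory(model, 2.0, n, bw, gaussian)
        bias = entropy_bias_theory(model, 2.0, n, bw, gaussian)
        beta_half = 1.0 / (1.0 - 0.125)
        sigma_sq = sigma_eta_sq_exact(model, 2.0, gaussian.CK, beta_half)
        assert mse == pytest.approx(bias ** 2 + sigma_sq / (n * bw.b_n),
                                    rel=1e-12)
        vals.append(mse)
    assert vals[0] > vals[1] > vals[2]
    assert vals[-1] < 0.01


def test_mse_theory_propagates_bias_flag(gaussian):
    model = exponential_model(1.0)
    assert mse_theory(model, 2.0, 100,
                      make_bandwidths(1.0, 0.5, 100), gaussian) is None


def test_proposition_error_decomposition_shrinks(gaussian):
    """The exact DCRTE estimation error and its first-order linearisation
    (from the stored Mhat/Ahat components and the exact M/A) agree up to
    terms that vanish with n: the median absolute discrepancy shrinks
    across n in {200, 1000, 5000}."""
    model = exponential_model(1.0)
    alpha, t = 2.0, 0.5
    exact = dcrte_exact(model, alpha, t)
    m_exact = math.exp(-2.0 * t) / 2.0
    a_exact = math.exp(-t) ** alpha
    medians = []
    for n in (200, 1000, 5000):
        bw = make_bandwidths(1.0, 0.5, n)
        cfg = EntropyConfig(alpha=alpha, t=t, compute_se=False,
                            grid_points=1024)
        discrepancies = []
        for rep in range(10):
            spec = ProcessSpec(family="iid", marginal="exponential",
                               marginal_params={"lam": 1.0}, n=n,
                               seed=55, stream=rep)
            est = dcrte_estimate(generate(spec), gaussian, bw, cfg)
            m_hat, a_hat = est.components
            true_error = est.value - exact
            linearised = -(1.0 / (alpha - 1.0)) * (
                (m_hat - a_hat * m_exact / a_exact) / a_exact)
            discrepancies.append(abs(true_error - linearised))
        medians.append(np.median(discrepancies))
    assert medians[0] > medians[2]
    assert medians[1] > medians[2]


def test_monte_carlo_variance_vs_first_order_formula(gaussian):
    """The first-order variance sigma_eta^2/(n*b_n) is a conservative
    envelope for the estimator's Monte Carlo variance, which follows the
    parametric 1/n rate (integrating the kernel density smooths away the
    1/(n*b_n) density-level rate)."""
    model = exponential_model(1.0)
    alpha = 2.0
    cfg = EntropyConfig(alpha=alpha, compute_se=False, grid_points=512)
    variances = {}
    for n in (250, 1000):
        bw = make_bandwidths(1.0, 0.5, n)
        vals = []
        for rep in range(120):
            spec = ProcessSpec(family="iid", marginal="exponential",
                               marginal_params={"lam": 1.0}, n=n,
                               seed=77, stream=rep)
            vals.append(crte_estimate(generate(spec), gaussian, bw, cfg).value)
        variances[n] = np.var(vals, ddof=1)
    sigma_sq = sigma_eta_sq_exact(model, alpha, gaussian.CK, BETA_HALF)
    for n, v in variances.items():
        first_order = sigma_sq / (n * n ** -0.5)
        assert v < first_order          # envelope
        assert v > 0.01 * first_order   # but not degenerate
    ratio = variances[250] / variances[1000]
    assert 2.0 < ratio < 8.0            # ~ 1/n scaling (factor 4)
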