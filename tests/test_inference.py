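"""Gamma likelihood, SRP maximum-likelihood fitting, and TM grid search."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import expit

from stpfit.inference import (FitResult, SRPEstimator, TMEstimator, fit_srp,
                              fit_tm, gamma_nll, predict_heldout, srp_nll)
from stpfit.kernels import Kernel
from stpfit.spiketrains import poisson_train, regular_train
from stpfit.srp import (SRPParameters, mean_efficacies, sample_efficacies,
                        sd_efficacies)
from stpfit.stats import poisson_surrogate_parameters
from stpfit.tm import TMParameters, tm_efficacies


# -- gamma negative log-likelihood ------------------------------------------

def test_gamma_nll_exponential_special_case():
    # mean = SD = 1 is the unit exponential: -log p(1) = 1
    assert gamma_nll([1.0], [1.0], [1.0]) == pytest.approx(1.0, abs=1e-12)


def test_gamma_nll_matches_independent_log_density(rng):
    y = rng.uniform(0.05, 5.0, 200)
    mu = rng.uniform(0.1, 3.0, 200)
    sig = rng.uniform(0.05, 2.0, 200)
    oracle = -np.sum(sps.gamma.logpdf(y, a=mu**2 / sig**2, scale=sig**2 / mu))
    assert gamma_nll(y, mu, sig) == pytest.approx(oracle, abs=1e-10)


def test_gamma_nll_skips_missing_and_rejects_nonpositive():
    base = gamma_nll([1.0, 2.0], [1.0, 1.5], [0.5, 0.5])
    with_nan = gamma_nll([1.0, np.nan, 2.0], [1.0, 1.0, 1.5], [0.5, 0.5, 0.5])
    assert with_nan == pytest.approx(base, abs=1e-12)
    with pytest.raises(ValueError):
        gamma_nll([-1.0], [1.0], [1.0])
    with pytest.raises(ValueError):
        gamma_nll([1.0], [0.0], [1.0])
    with pytest.raises(ValueError):
        gamma_nll([1.0], [1.0], [-0.5])


def test_gamma_nll_minimized_near_sample_mean(rng):
    # 1-D scan over mu at fixed CV: the ML mean tracks the sample mean
    true_mu, cv = 1.4, 0.3
    y = rng.gamma((1 / cv) ** 2, cv**2 * true_mu, size=20_000)
    grid = np.linspace(0.8, 2.0, 481)
    nlls = [gamma_nll(y, np.full_like(y, m), np.full_like(y, cv * m))
            for m in grid]
    assert grid[int(np.argmin(nlls))] == pytest.approx(y.mean(), abs=0.01)


# -- SRP likelihood over protocols ------------------------------------------

def test_srp_nll_zero_sigma_kernel_reduces_to_constant_sd(mono_exp_params):
    tr = regular_train(50.0, 6)
    p = SRPParameters(
        mu_kernel=mono_exp_params.mu_kernel,
        sigma_kernel=Kernel.exponential([0.1], [0.0], baseline=-1.5),
        sigma_scale=1.5)
    y = sample_efficacies(p, tr, 20, seed=1)
    mus = mean_efficacies(p, tr)
    const_sd = 1.5 * expit(-1.5)
    by_hand = gamma_nll(y, mus, np.full_like(mus, const_sd))
    assert srp_nll(p, tr, y) == pytest.approx(by_hand, rel=1e-12)


def test_srp_nll_lower_at_generating_parameters(mono_exp_params, rng):
    train = poisson_train(10.0, 1000, seed=3)
    y = sample_efficacies(mono_exp_params, train, 1, seed=4)
    nll_true = srp_nll(mono_exp_params, train, y)
    k = mono_exp_params.mu_kernel
    ks = mono_exp_params.sigma_kernel
    worse = 0
    for _ in range(100):
        pert = rng.uniform(0.8, 1.2, size=5)
        p = SRPParameters(
            mu_kernel=Kernel.exponential([0.1], [k.amplitudes[0] * pert[0]],
                                         baseline=k.baseline * pert[1]),
            sigma_kernel=Kernel.exponential([0.1], [ks.amplitudes[0] * pert[2]],
                                            baseline=ks.baseline * pert[3]),
            sigma_scale=mono_exp_params.sigma_scale * pert[4])
        worse += srp_nll(p, train, y) > nll_true
    assert worse == 100


def test_likelihood_landscape_has_single_interior_minimum(mono_exp_params):
    # scan the (mu-amplitude, sigma-amplitude) plane around the optimum on
    # surrogate data: one local minimum, away from the box edge
    train = poisson_train(10.0, 1500, seed=8)
    y = sample_efficacies(mono_exp_params, train, 1, seed=9)
    a0 = mono_exp_params.mu_kernel.amplitudes[0]
    c0 = mono_exp_params.sigma_kernel.amplitudes[0]
    grid_a = np.linspace(0.5 * a0, 1.5 * a0, 15)
    grid_c = np.linspace(0.5 * c0, 1.5 * c0, 15)
    nll = np.empty((15, 15))
    for i, a in enumerate(grid_a):
        for j, c in enumerate(grid_c):
            p = SRPParameters(
                mu_kernel=Kernel.exponential([0.1], [a], baseline=-1.5),
                sigma_kernel=Kernel.exponential([0.1], [c], baseline=-1.5),
                sigma_scale=1.5)
            nll[i, j] = srp_nll(p, train, y)
    local_minima = 0
    for i in range(1, 14):
        for j in range(1, 14):
            patch = nll[i - 1: i + 2, j - 1: j + 2]
            if nll[i, j] == patch.min():
                local_minima += 1
    assert local_minima == 1
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    assert 0 < i < 14 and 0 < j < 14


# -- SRP fitting -------------------------------------------------------------

def test_fit_is_deterministic_under_seed(mono_exp_params):
    train = poisson_train(10.0, 300, seed=0)
    y = sample_efficacies(mono_exp_params, train, 1, seed=1)
    kwargs = dict(basis_taus=(0.1,), n_starts=4, random_state=77)
    est1 = SRPEstimator(**kwargs).fit(train, y)
    est2 = SRPEstimator(**kwargs).fit(train, y)
    np.testing.assert_array_equal(est1.theta_, est2.theta_)
    assert est1.nll_ == est2.nll_


def test_fit_recovers_and_refits_self_consistently(mono_exp_params):
    train = poisson_train(10.0, 1500, seed=21)
    y = sample_efficacies(mono_exp_params, train, 1, seed=22)
    est = SRPEstimator(basis_taus=(0.1,), n_starts=16, random_state=5)
    est.fit(train, y)
    # data re-generated from the fitted model refits to the same parameters
    y2 = sample_efficacies(est.params_, train, 1, seed=23)
    est2 = SRPEstimator(basis_taus=(0.1,), n_starts=16, random_state=6)
    est2.fit(train, y2)
    np.testing.assert_allclose(est2.theta_, est.theta_, rtol=0.15, atol=0.05)


def test_fitted_parameters_respect_bounds(mono_exp_params):
    train = poisson_train(10.0, 400, seed=31)
    y = sample_efficacies(mono_exp_params, train, 1, seed=32)
    est = SRPEstimator(basis_taus=(0.1,), n_starts=4, random_state=1)
    est.fit(train, y)
    lo, hi = est._bounds()
    assert np.all(est.theta_ >= lo) and np.all(est.theta_ <= hi)
    assert est.result_.converged
    assert np.isfinite(est.result_.objective)
    assert est.result_.start_values.shape == (4, lo.size)


def test_standardized_mode_has_eight_parameters():
    est = SRPEstimator(fit_sigma_scale=False)
    assert len(est._layout()[3]) == 8
    est_full = SRPEstimator()
    assert len(est_full._layout()[3]) == 9


def test_fit_requires_multi_pulse_protocol(mono_exp_params):
    tr = regular_train(10.0, 1)
    with pytest.raises(ValueError):
        SRPEstimator().fit(tr, np.array([[1.0]]))


def test_nonpositive_amplitudes_are_excluded_with_warning(mono_exp_params):
    train = regular_train(20.0, 5)
    y = sample_efficacies(mono_exp_params, train, 8, seed=2)
    y[0, 0] = -0.5
    est = SRPEstimator(basis_taus=(0.1,), n_starts=2, random_state=0)
    with pytest.warns(UserWarning, match="non-positive"):
        est.fit(train, y)


def test_sklearn_param_interface():
    est = SRPEstimator(n_starts=4)
    params = est.get_params()
    assert params["n_starts"] == 4
    est.set_params(n_starts=8, variance_mode="constant")
    assert est.n_starts == 8 and est.variance_mode == "constant"


# -- TM grid search ----------------------------------------------------------

def test_tm_grid_recovers_on_grid_truth_exactly():
    est = TMEstimator(n_grid=(5, 5, 5, 5), U_range=(0.1, 0.5),
                      f_range=(0.1, 0.5), tau_u_range=(0.05, 0.8),
                      tau_R_range=(0.05, 0.8))
    U, f, tu, tR = est._grid_axes()
    truth = TMParameters(U[2], f[1], tu[3], tR[2])
    trains = [regular_train(20.0, 8), regular_train(100.0, 8)]
    ys = [tm_efficacies(truth, tr) for tr in trains]
    est.fit(trains, ys)
    assert est.params_ == truth
    assert est.mse_ == 0.0


def test_tm_grid_off_grid_truth_within_one_cell():
    est = TMEstimator(n_grid=(9, 9, 9, 9), U_range=(0.1, 0.5),
                      f_range=(0.1, 0.5), tau_u_range=(0.05, 0.8),
                      tau_R_range=(0.05, 0.8))
    truth = TMParameters(0.23, 0.31, 0.13, 0.41)
    trains = [regular_train(20.0, 8), regular_train(100.0, 8),
              regular_train(50.0, 8)]
    ys = [tm_efficacies(truth, tr) for tr in trains]
    est.fit(trains, ys)
    U, f, tu, tR = est._grid_axes()
    assert abs(est.params_.U - truth.U) <= np.diff(U).max()
    assert abs(est.params_.f - truth.f) <= np.diff(f).max()
    assert est.params_.tau_u / truth.tau_u < tu[1] / tu[0] * 1.01
    assert truth.tau_u / est.params_.tau_u < tu[1] / tu[0] * 1.01
    # oracle: the argmin is at least as good as the grid point nearest truth
    snap = TMParameters(
        U[np.argmin(abs(U - truth.U))], f[np.argmin(abs(f - truth.f))],
        tu[np.argmin(abs(tu - truth.tau_u))],
        tR[np.argmin(abs(tR - truth.tau_R))])
    mse_snap = np.mean([np.mean((tm_efficacies(snap, tr) - y) ** 2)
                        for tr, y in zip(trains, ys)])
    assert est.mse_ <= mse_snap + 1e-12


def test_tm_grid_smoke_on_standard_protocols(mono_exp_params):
    trains = [regular_train(20.0, 10), regular_train(100.0, 10)]
    ys = [sample_efficacies(mono_exp_params, tr, 10, seed=i)
          for i, tr in enumerate(trains)]
    est = TMEstimator(n_grid=(10, 10, 10, 10))
    est.fit(trains, ys)
    assert np.isfinite(est.mse_)
    assert isinstance(est.params_, TMParameters)


def test_tm_normalized_mode_tracks_facilitating_normalized_data(mono_exp_params):
    # normalized-prediction mode: first pulse is 1 and facilitation > 1 is
    # reachable, which the raw (bounded-by-one) efficacy R*u never is
    tr = regular_train(100.0, 5)
    target = mean_efficacies(mono_exp_params, tr)
    est = TMEstimator(n_grid=(8, 8, 8, 8), normalize_first_pulse=True)
    est.fit([tr], [target])
    pred = est.predict(tr)
    assert pred[0] == pytest.approx(1.0)
    assert pred.max() > 1.0
    raw = TMEstimator(n_grid=(8, 8, 8, 8)).fit([tr], [target])
    assert est.mse_ < raw.mse_


def test_tm_empty_grid_rejected():
    est = TMEstimator(n_grid=(0, 5, 5, 5))
    with pytest.raises(ValueError):
        est.fit([regular_train(20.0, 4)], [np.ones(4)])


# -- prediction --------------------------------------------------------------

def test_predict_matches_mean_efficacies(mono_exp_params):
    train = poisson_train(10.0, 300, seed=51)
    y = sample_efficacies(mono_exp_params, train, 1, seed=52)
    est = SRPEstimator(basis_taus=(0.1,), n_starts=4, random_state=2)
    est.fit(train, y)
    held = regular_train(100.0, 10)
    np.testing.assert_array_equal(est.predict(held),
                                  mean_efficacies(est.params_, held))
    np.testing.assert_array_equal(est.predict_sd(held),
                                  sd_efficacies(est.params_, held))
    mu, sd = predict_heldout(est.result_, held)
    np.testing.assert_array_equal(mu, est.predict(held))


def test_srp_and_tm_predictions_share_layout(mono_exp_params):
    held = regular_train(50.0, 6)
    tm_fit = FitResult(parameters=TMParameters(0.2, 0.1, 0.1, 0.5),
                       objective=0.0)
    tm_pred = predict_heldout(tm_fit, held)
    srp_fit = FitResult(parameters=mono_exp_params, objective=0.0)
    srp_mu, srp_sd = predict_heldout(srp_fit, held)
    assert tm_pred.shape == srp_mu.shape == srp_sd.shape


def test_functional_wrappers_return_fit_results(mono_exp_params):
    train = poisson_train(10.0, 200, seed=61)
    y = sample_efficacies(mono_exp_params, train, 1, seed=62)
    res = fit_srp(train, y, basis_taus=(0.1,), n_starts=2, seed=3)
    assert isinstance(res, FitResult)
    assert res.n_starts == 2
    trains = [regular_train(20.0, 6)]
    res_tm = fit_tm(trains, [tm_efficacies(TMParameters(0.2, 0.2, 0.1, 0.5),
                                           trains[0])],
                    n_grid=(4, 4, 4, 4))
    assert isinstance(res_tm.parameters, TMParameters)
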