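"""Fitting machinery: gradients, BIC arithmetic, determinism, recovery."""

import numpy as np
import pytest

from conftest import SMALL_P, SMALL_STATES
from tensorsig.inference import (
    FitConfig,
    _forward_backward,
    bic,
    fit,
    init_params,
    model_to_params,
    parameter_count,
    params_to_model,
)
from tensorsig.model import assemble_signature_tensor
from tensorsig.simulate import TruthPriors, sample_counts, sample_truth


class TestParameterCount:
    def test_documented_example(self):
        # 4*95 + 4 + 1 + (15 + 3 + 1) + 9 per signature, plus exposures
        assert parameter_count(1, p=96, q=10, n=5) == 418

    def test_linear_in_rank(self):
        k1 = parameter_count(3, p=96, q=12, n=40)
        assert parameter_count(6, p=96, q=12, n=40) == 2 * k1

    def test_boundary_arithmetic(self):
        # p=1, q=1, n=0: 4*0 + 4 + 1 + 19 + 0 = 24 per signature
        assert parameter_count(5, p=1, q=1, n=0) == 5 * 24


class TestBic:
    def test_arithmetic(self):
        assert bic(-500.0, 10, 100) == pytest.approx(10 * np.log(100) + 1000)

    def test_zero_parameters(self):
        assert bic(-123.0, 0, 50) == pytest.approx(246.0)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            bic(0.0, 1, 0)


@pytest.fixture(scope="module")
def tiny_problem():
    truth = sample_truth(
        2, 3, seed=41, state_sizes=SMALL_STATES, p=SMALL_P,
        priors=TruthPriors(mutations_per_sample=300.0, n_categories=4),
    )
    snv, oth = sample_counts(truth, seed=42)
    return truth, snv, oth


class TestGradients:
    def test_analytic_matches_finite_differences(self, tiny_problem):
        _, snv, oth = tiny_problem
        n = snv.counts.shape[-1]
        c_flat = np.ascontiguousarray(snv.counts.reshape(-1, n).astype(float))
        c_oth = np.ascontiguousarray(oth.counts.astype(float))
        rng = np.random.default_rng(1)
        params = init_params(
            rng, 2, SMALL_P, c_oth.shape[0], n, SMALL_STATES,
            c_flat.sum(0) + c_oth.sum(0), 0.8,
        )
        buffers = {"d_tflat": np.empty((c_flat.shape[0], 2)),
                   "d_e_ns": np.empty((n, 2))}
        _, grads = _forward_backward(
            params, c_flat, c_oth, 50.0, SMALL_STATES, SMALL_P, buffers, True
        )
        h = 1e-6
        for key in params:
            flat_idx = rng.choice(params[key].size, size=min(5, params[key].size),
                                  replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, params[key].shape)
                pp = {k: v.copy() for k, v in params.items()}
                pp[key][ix] += h
                lp, _ = _forward_backward(pp, c_flat, c_oth, 50.0, SMALL_STATES,
                                          SMALL_P, buffers, True)
                pp[key][ix] -= 2 * h
                lm, _ = _forward_backward(pp, c_flat, c_oth, 50.0, SMALL_STATES,
                                          SMALL_P, buffers, True)
                numeric = (lp - lm) / (2 * h)
                assert grads[key][ix] == pytest.approx(numeric, rel=1e-3, abs=1e-4), key


class TestParametrisation:
    def test_roundtrip_through_free_scale(self, tiny_problem):
        truth, _, _ = tiny_problem
        params = model_to_params(truth.core, truth.factors, truth.exposures)
        core, factors, exposures = params_to_model(params)
        np.testing.assert_allclose(core.t0, truth.core.t0, rtol=1e-6)
        np.testing.assert_allclose(factors.b_t, truth.factors.b_t, rtol=1e-9)
        np.testing.assert_allclose(factors.k_epi, truth.factors.k_epi, rtol=1e-9)
        np.testing.assert_allclose(exposures.e, truth.exposures.e, rtol=1e-6)

    def test_constraints_hold_for_any_free_values(self):
        rng = np.random.default_rng(2)
        params = init_params(rng, 3, SMALL_P, 4, 5, SMALL_STATES,
                             np.full(5, 100.0), 0.9)
        for key in params:
            params[key] = params[key] + rng.normal(0, 3, params[key].shape)
        core, factors, exposures = params_to_model(params)
        np.testing.assert_allclose(core.t0.sum(axis=2), 1.0)
        assert (factors.k_epi[0] == 1).all()
        assert ((factors.m >= 0) & (factors.m <= 1)).all()
        assert (exposures.e >= 0).all()


@pytest.fixture(scope="module")
def fitted(tiny_problem):
    _, snv, oth = tiny_problem
    cfg = FitConfig(rank=2, epochs=800, n_init=2, seed=3, lr=0.1)
    return fit(snv, oth, cfg)


class TestFit:
    def test_determinism(self, tiny_problem, fitted):
        _, snv, oth = tiny_problem
        again = fit(snv, oth, FitConfig(rank=2, epochs=800, n_init=2, seed=3, lr=0.1))
        assert abs(again.loglik - fitted.loglik) < 1e-8

    def test_loss_decreases_after_burn_in(self, fitted):
        losses = [v for _, v in fitted.trace]
        burn = max(1, len(losses) // 100)
        tail = losses[burn:]
        # smoke check: the recorded loss is non-increasing within jitter
        for a, b in zip(tail, tail[1:]):
            assert b <= a + abs(a) * 1e-4

    def test_refit_from_optimum_is_stable(self, tiny_problem, fitted):
        _, snv, oth = tiny_problem
        warm = model_to_params(fitted.core, fitted.factors, fitted.exposures)
        cfg = FitConfig(rank=2, epochs=50, n_init=1, seed=3, lr=1e-4,
                        lr_final=1e-5)
        refit = fit(snv, oth, cfg, init=warm)
        assert abs(refit.loglik - fitted.loglik) < 1e-3 * abs(fitted.loglik) + 1.0

    def test_fitted_totals_match_observed(self, tiny_problem, fitted):
        """Scale identifiability: expected totals track observed totals."""
        _, snv, oth = tiny_problem
        t = assemble_signature_tensor(fitted.core, fitted.factors)
        from tensorsig.model import expected_counts

        mu_snv, mu_oth = expected_counts(
            t, fitted.factors.s0, fitted.factors.m, fitted.exposures
        )
        fit_tot = mu_snv.sum(axis=tuple(range(6))) + mu_oth.sum(axis=0)
        obs_tot = (snv.counts.sum(axis=tuple(range(6)))
                   + oth.counts.sum(axis=0)).astype(float)
        np.testing.assert_allclose(fit_tot, obs_tot, rtol=0.05)

    def test_bic_consistent_with_parameter_count(self, tiny_problem, fitted):
        _, snv, oth = tiny_problem
        n_obs = int(snv.counts.sum() + oth.counts.sum())
        k = parameter_count(2, p=SMALL_P, q=oth.counts.shape[0],
                           n=snv.counts.shape[-1], state_sizes=SMALL_STATES)
        assert fitted.bic == pytest.approx(bic(fitted.loglik, k, n_obs))

    def test_single_signature_recovery(self):
        """Data from a 1-signature model: fitted spectrum cosine > 0.99."""
        truth = sample_truth(
            1, 20, seed=50, state_sizes=(4, 4, 2),
            priors=TruthPriors(mutations_per_sample=3000.0),
        )
        snv, oth = sample_counts(truth, seed=51)
        f = fit(snv, oth, FitConfig(rank=1, epochs=400, n_init=1, seed=1))
        a = truth.core.t0.reshape(-1)
        b = f.core.t0.reshape(-1)
        cosine = a @ b / np.linalg.norm(a) / np.linalg.norm(b)
        assert cosine > 0.99

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(rank=0)
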