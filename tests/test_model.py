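"""Signature-tensor assembly and the negative-binomial likelihood.

The assembly is checked against an independent nested-loop scalar
evaluation; the likelihood against an arbitrary-precision oracle and its
Poisson limit.
"""

import numpy as np
import pytest

from conftest import SMALL_P, SMALL_STATES, random_core, random_factors
from tensorsig.model import (
    CoreSpectra,
    Dispersion,
    ExposureMatrix,
    SignatureTensor,
    TensorFactors,
    activity_tensor,
    assemble_signature_tensor,
    bias_tensor,
    broadcast_multiply,
    expected_counts,
    nb_logpmf,
    nb_loglik,
    signature_posterior,
    stack_t1,
)


def loop_assemble(core, factors):
    """Oracle: scalar evaluation of every tensor entry with explicit loops."""
    t1 = stack_t1(core)
    s = factors.rank
    te, tn, tc = factors.state_sizes
    p = core.n_channels
    bias_exp = [1, -1, 0]
    act_exp = [1, 1, 0]
    out = np.empty((3, 3, te, tn, tc, p, s))
    for i in range(3):
        for j in range(3):
            for e in range(te):
                for u in range(tn):
                    for c in range(tc):
                        for ch in range(p):
                            for sig in range(s):
                                out[i, j, e, u, c, ch, sig] = (
                                    t1[i, j, ch, sig]
                                    * factors.b_t[sig] ** bias_exp[i]
                                    * factors.b_r[sig] ** bias_exp[j]
                                    * factors.a_t[sig] ** act_exp[i]
                                    * factors.a_r[sig] ** act_exp[j]
                                    * factors.m[sig]
                                    * factors.k_epi[e, sig]
                                    * factors.k_nuc[u, sig]
                                    * factors.k_clu[c, sig]
                                )
    return out


class TestBroadcastMultiply:
    def test_row_times_column(self):
        out = broadcast_multiply(np.array([[1, 2]]), np.array([[3], [4]]))
        np.testing.assert_array_equal(out, [[3, 6], [4, 8]])

    def test_identity_with_ones(self):
        x = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(broadcast_multiply(x, np.ones((1, 4))), x)

    def test_incompatible_shapes_rejected(self):
        with pytest.raises(ValueError):
            broadcast_multiply(np.ones((2, 2)), np.ones((1, 1, 3)))

    def test_singleton_expansion_valid(self):
        out = broadcast_multiply(np.ones((2, 2, 1)), np.ones((1, 1, 3)))
        assert out.shape == (2, 2, 3)


class TestStackT1:
    def test_identical_spectra_everywhere(self):
        spec = np.full((96, 1), 1 / 96)
        core = CoreSpectra(np.broadcast_to(spec, (2, 2, 96, 1)).copy())
        t1 = stack_t1(core)
        for i in range(3):
            for j in range(3):
                np.testing.assert_allclose(t1[i, j], spec)

    def test_unknown_replication_block_is_mean(self):
        rng = np.random.default_rng(0)
        core = CoreSpectra(random_core(rng))
        t1 = stack_t1(core)
        np.testing.assert_allclose(
            t1[0, 2], 0.5 * (core.t0[0, 0] + core.t0[0, 1])
        )

    def test_matches_independent_evaluation(self):
        """Every block from an explicitly indexed re-implementation."""
        rng = np.random.default_rng(1)
        core = CoreSpectra(random_core(rng))
        cl, cg, tl, tg = (core.t0[0, 0], core.t0[0, 1],
                          core.t0[1, 0], core.t0[1, 1])
        expected = {
            (0, 0): cl, (0, 1): cg, (0, 2): (cl + cg) / 2,
            (1, 0): tl, (1, 1): tg, (1, 2): (tl + tg) / 2,
            (2, 0): (cl + tl) / 2, (2, 1): (cg + tg) / 2,
            (2, 2): (cl + cg + tl + tg) / 4,
        }
        t1 = stack_t1(core)
        for (i, j), block in expected.items():
            np.testing.assert_allclose(t1[i, j], block)


class TestBiasAndActivity:
    def test_neutral_biases_give_ones(self):
        np.testing.assert_array_equal(
            bias_tensor(np.ones(2), np.ones(2)), np.ones((3, 3, 1, 2))
        )

    def test_transcription_bias_layout(self):
        b = bias_tensor(np.array([2.0]), np.array([1.0]))[:, :, 0, 0]
        np.testing.assert_allclose(
            b, [[2, 2, 2], [0.5, 0.5, 0.5], [1, 1, 1]]
        )

    def test_diagonal_product_identity(self):
        rng = np.random.default_rng(2)
        b = bias_tensor(np.exp(rng.normal(size=3)), np.exp(rng.normal(size=3)))
        np.testing.assert_allclose(
            b[0, 0, 0] * b[1, 1, 0], b[0, 1, 0] * b[1, 0, 0]
        )

    def test_activity_layout(self):
        a = activity_tensor(np.array([3.0]), np.array([2.0]))[:, :, 0, 0]
        np.testing.assert_allclose(
            a, [[6, 6, 3], [6, 6, 3], [2, 2, 1]]
        )


class TestAssembly:
    def test_neutral_factors_reduce_to_spectrum(self):
        spec = np.full((SMALL_P, 1), 1 / SMALL_P)
        core = CoreSpectra(np.broadcast_to(spec, (2, 2, SMALL_P, 1)).copy())
        te, tn, tc = SMALL_STATES
        factors = TensorFactors(
            b_t=[1.0], b_r=[1.0], a_t=[1.0], a_r=[1.0], m=[1.0],
            k_epi=np.ones((te, 1)), k_nuc=np.ones((tn, 1)),
            k_clu=np.ones((tc, 1)), s0=np.ones((2, 1)) / 2,
        )
        t = assemble_signature_tensor(core, factors).t
        np.testing.assert_allclose(
            t, np.broadcast_to(spec, t.shape), atol=1e-12
        )

    def test_worked_entry(self):
        """coding x unknown-replication entry: b_t a_t m (T0_CL+T0_CG)/2 k."""
        rng = np.random.default_rng(3)
        core = CoreSpectra(random_core(rng))
        factors = random_factors(rng)
        t = assemble_signature_tensor(core, factors).t
        j_epi = 2
        expected = (
            factors.b_t * factors.a_t * factors.m
            * 0.5 * (core.t0[0, 0] + core.t0[0, 1])
            * factors.k_epi[j_epi]
        )
        np.testing.assert_allclose(t[0, 2, j_epi, 0, 0], expected)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            core = CoreSpectra(random_core(rng))
            factors = random_factors(rng)
            fast = assemble_signature_tensor(core, factors).t
            slow = loop_assemble(core, factors)
            rel = np.abs(fast - slow) / np.maximum(np.abs(slow), 1e-300)
            assert rel.max() < 1e-10

    def test_baseline_row_violation_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="baseline"):
            factors = random_factors(rng)
            bad = factors.k_epi.copy()
            bad[0] = 2.0
            TensorFactors(
                b_t=factors.b_t, b_r=factors.b_r, a_t=factors.a_t,
                a_r=factors.a_r, m=factors.m, k_epi=bad,
                k_nuc=factors.k_nuc, k_clu=factors.k_clu, s0=factors.s0,
            )


class TestExpectedCounts:
    def test_zero_exposure_zero_mean(self):
        rng = np.random.default_rng(6)
        core = CoreSpectra(random_core(rng))
        factors = random_factors(rng)
        t = assemble_signature_tensor(core, factors)
        mu_snv, mu_oth = expected_counts(
            t, factors.s0, factors.m, ExposureMatrix(np.zeros((2, 3)))
        )
        assert mu_snv.sum() == 0 and mu_oth.sum() == 0

    def test_total_mass_bookkeeping(self):
        """With one signature at exposure 1000, total expected counts are
        1000 * (tensor mass + (1 - m)); m splits SNV from other mass."""
        rng = np.random.default_rng(7)
        core = CoreSpectra(random_core(rng, s=1))
        factors = random_factors(rng, s=1)
        t = assemble_signature_tensor(core, factors)
        e = ExposureMatrix(np.array([[1000.0]]))
        mu_snv, mu_oth = expected_counts(t, factors.s0, factors.m, e)
        assert mu_snv.sum() == pytest.approx(1000 * t.t.sum())
        assert mu_oth.sum() == pytest.approx(1000 * (1 - factors.m[0]))

    def test_matches_loop_evaluation(self):
        rng = np.random.default_rng(8)
        core = CoreSpectra(random_core(rng))
        factors = random_factors(rng)
        t = assemble_signature_tensor(core, factors)
        e = ExposureMatrix(rng.random((2, 3)) * 100)
        mu_snv, _ = expected_counts(t, factors.s0, factors.m, e)
        flat = t.t.reshape(-1, 2)
        loop = np.zeros((flat.shape[0], 3))
        for d in range(flat.shape[0]):
            for n in range(3):
                for s in range(2):
                    loop[d, n] += flat[d, s] * e.e[s, n]
        np.testing.assert_allclose(mu_snv.reshape(-1, 3), loop, rtol=1e-12)


class TestNbLoglik:
    def test_zero_counts_closed_form(self):
        mu = np.array([0.5, 2.0, 7.0])
        tau = 3.0
        expected = (tau * np.log(tau / (tau + mu))).sum()
        assert nb_loglik(np.zeros(3), mu, None, None, tau) == pytest.approx(expected)

    def test_poisson_limit(self):
        """tau -> 1e8 approaches the Poisson log-likelihood per entry."""
        from scipy.stats import poisson

        rng = np.random.default_rng(9)
        mu = rng.uniform(0.1, 20, size=50)
        c = rng.poisson(mu)
        nb = nb_logpmf(c, mu, 1e8)
        po = poisson.logpmf(c, mu)
        assert np.abs(nb - po).max() < 1e-4

    def test_matches_arbitrary_precision(self):
        """20 random instances against an mpmath evaluation of the NB PMF."""
        import mpmath as mp

        mp.mp.dps = 50
        rng = np.random.default_rng(10)
        for _ in range(20):
            shape = (3, 2)
            mu = rng.uniform(0.01, 30, size=shape)
            tau = float(rng.uniform(0.5, 200))
            c = rng.poisson(mu).astype(float)
            ours = nb_logpmf(c, mu, tau).sum()
            exact = mp.mpf(0)
            for cij, mij in zip(c.ravel(), mu.ravel()):
                t = mp.mpf(tau)
                mij = mp.mpf(mij)
                term = (
                    mp.loggamma(t + cij) - mp.loggamma(t) - mp.loggamma(cij + 1)
                    + t * mp.log(t / (t + mij))
                    + cij * mp.log(mij / (t + mij))
                )
                exact += term
            assert abs(ours - float(exact)) < 1e-8

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError):
            nb_logpmf(np.array([1.0]), np.array([np.nan]), 10.0)

    def test_permutation_invariance(self):
        """Relabelling signatures jointly in (T, S0, E) leaves log L fixed."""
        rng = np.random.default_rng(11)
        core = CoreSpectra(random_core(rng, s=3))
        factors = random_factors(rng, s=3)
        e = ExposureMatrix(rng.random((3, 4)) * 50)
        t = assemble_signature_tensor(core, factors)
        mu1 = expected_counts(t, factors.s0, factors.m, e)
        perm = [2, 0, 1]
        core2 = CoreSpectra(core.t0[..., perm])
        factors2 = random_factors(rng, s=3)  # replaced below field by field
        factors2 = TensorFactors(
            b_t=factors.b_t[perm], b_r=factors.b_r[perm],
            a_t=factors.a_t[perm], a_r=factors.a_r[perm], m=factors.m[perm],
            k_epi=factors.k_epi[:, perm], k_nuc=factors.k_nuc[:, perm],
            k_clu=factors.k_clu[:, perm], s0=factors.s0[:, perm],
        )
        e2 = ExposureMatrix(e.e[perm])
        t2 = assemble_signature_tensor(core2, factors2)
        mu2 = expected_counts(t2, factors2.s0, factors2.m, e2)
        c_snv = rng.poisson(mu1[0])
        c_oth = rng.poisson(mu1[1])
        ll1 = nb_loglik(c_snv, mu1[0], c_oth, mu1[1], 20.0)
        ll2 = nb_loglik(c_snv, mu2[0], c_oth, mu2[1], 20.0)
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_dispersion_validation(self):
        with pytest.raises(ValueError):
            Dispersion(0.0)


class TestDegeneracyReduction:
    def test_marginal_equals_rank_s_nmf_product(self):
        """With neutral factors and shared spectra, the channel x sample
        marginal of the expected SNV tensor equals a plain rank-s NMF
        reconstruction scaled by the exact state multiplicity."""
        rng = np.random.default_rng(12)
        s = 2
        spec = rng.random((SMALL_P, s)) + 0.1
        spec /= spec.sum(axis=0, keepdims=True)
        core = CoreSpectra(np.broadcast_to(spec, (2, 2, SMALL_P, s)).copy())
        te, tn, tc = SMALL_STATES
        factors = TensorFactors(
            b_t=np.ones(s), b_r=np.ones(s), a_t=np.ones(s), a_r=np.ones(s),
            m=np.ones(s), k_epi=np.ones((te, s)), k_nuc=np.ones((tn, s)),
            k_clu=np.ones((tc, s)), s0=np.ones((2, s)) / 2,
        )
        e = ExposureMatrix(rng.random((s, 4)) * 100)
        t = assemble_signature_tensor(core, factors)
        mu_snv, _ = expected_counts(t, factors.s0, factors.m, e)
        marginal = mu_snv.sum(axis=(0, 1, 2, 3, 4))  # (p, n)
        multiplicity = 9 * te * tn * tc
        np.testing.assert_allclose(marginal, multiplicity * (spec @ e.e), rtol=1e-10)


class TestSignaturePosterior:
    def _setup(self, rng, s):
        core = CoreSpectra(random_core(rng, s=s))
        factors = random_factors(rng, s=s)
        t = assemble_signature_tensor(core, factors)
        e = ExposureMatrix(rng.random((s, 3)) * 10)
        return t, e

    def test_single_signature_certain(self):
        rng = np.random.default_rng(13)
        t, e = self._setup(rng, 1)
        post, degenerate = signature_posterior(t, e, 2, (0, 1, 1, 0, 1), 0)
        assert post == pytest.approx([1.0])
        assert not degenerate

    def test_equal_intensity_symmetric(self):
        rng = np.random.default_rng(14)
        t, _ = self._setup(rng, 1)
        tt = np.concatenate([t.t, t.t], axis=-1)
        e = ExposureMatrix(np.ones((2, 1)))
        post, _ = signature_posterior(SignatureTensor(tt), e, 0, (0, 0, 0, 0, 0), 0)
        np.testing.assert_allclose(post, [0.5, 0.5])

    def test_matches_direct_bayes(self):
        rng = np.random.default_rng(15)
        t, e = self._setup(rng, 3)
        states, ch, n = (1, 2, 0, 1, 1), 3, 2
        post, _ = signature_posterior(t, e, ch, states, n)
        direct = np.array(
            [t.t[states + (ch, sig)] * e.e[sig, n] for sig in range(3)]
        )
        np.testing.assert_allclose(post, direct / direct.sum(), rtol=1e-12)

    def test_zero_intensity_uniform_flagged(self):
        rng = np.random.default_rng(16)
        t, _ = self._setup(rng, 2)
        e = ExposureMatrix(np.zeros((2, 1)))
        post, degenerate = signature_posterior(t, e, 0, (0, 0, 0, 0, 0), 0)
        np.testing.assert_allclose(post, [0.5, 0.5])
        assert degenerate
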