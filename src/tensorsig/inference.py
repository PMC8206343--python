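"""Maximum-likelihood fitting, BIC model selection and rank scans.

The negative-binomial likelihood is maximised by an adaptive-moment
(Adam) gradient ascent on an unconstrained parametrisation: spectra via
per-block softmax, positive scalars via exp, the SNV fraction via a
logistic, exposures via exp.  Gradients are derived analytically; the
dominant cost — the gradient of the likelihood through the (cells x
samples) mean array — runs in a fused, cache-friendly kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .catalogue import CountTensor, OtherCountMatrix
from .model import (
    MU_FLOOR,
    CoreSpectra,
    ExposureMatrix,
    SignatureTensor,
    TensorFactors,
    assemble_signature_tensor,
    expected_counts,
    nb_loglik,
)

log = logging.getLogger(__name__)

_BIAS_EXP = np.array([1.0, -1.0, 0.0])
_ACT_EXP = np.array([1.0, 1.0, 0.0])


@dataclass(frozen=True)
class FitConfig:
    """Optimiser settings.

    ``epochs`` defaults to a desk-scale budget; cohort-scale analyses use
    ~50,000.  The learning rate decays exponentially from ``lr`` to
    ``lr_final`` over the epoch budget.  ``n_init`` random restarts are
    fitted and the best log-likelihood kept.  ``tau`` is a fixed
    hyperparameter of the negative-binomial observation model.
    """

    rank: int
    tau: float = 50.0
    epochs: int = 5000
    lr: float = 0.1
    lr_final: float = 1e-3
    n_init: int = 5
    seed: int = 0
    trace_every: int = 100
    max_retries: int = 3

    def __post_init__(self) -> None:
        if self.rank < 1 or self.epochs < 1 or self.lr <= 0:
            raise ValueError("rank >= 1, epochs >= 1 and lr > 0 required")


@dataclass
class ModelFit:
    """A fitted model: constrained parameters, likelihood and BIC."""

    core: CoreSpectra
    factors: TensorFactors
    exposures: ExposureMatrix
    tau: float
    loglik: float
    bic: float
    config: FitConfig
    trace: list[tuple[int, float]] = field(default_factory=list)
    n_parameters: int = 0
    n_observations: int = 0

    @property
    def rank(self) -> int:
        return self.factors.rank

    def signature_tensor(self) -> SignatureTensor:
        return assemble_signature_tensor(self.core, self.factors)


@dataclass
class RankScan:
    """Best fit and BIC per candidate rank; selection = argmin BIC."""

    fits: list[ModelFit]

    @property
    def bics(self) -> np.ndarray:
        return np.array([f.bic for f in self.fits])

    @property
    def selected_rank(self) -> int:
        return self.fits[int(np.argmin(self.bics))].rank


# ---------------------------------------------------------------------------
# BIC


def parameter_count(
    s: int,
    p: int = 96,
    q: int = 0,
    n: int = 0,
    state_sizes: tuple[int, ...] = (16, 4, 2),
) -> int:
    """Number of free parameters at rank ``s``.

    Per signature: 4 normalised spectra contribute 4(p-1); the strand
    biases and amplitudes 4; the SNV fraction 1; each state axis with
    ``t_j`` states contributes t_j - 1 free rows (the baseline row is
    fixed); the normalised other-type spectrum q - 1.  Exposures add
    s * n.
    """
    per_sig = 4 * (p - 1) + 4 + 1 + sum(t - 1 for t in state_sizes)
    if q > 0:
        per_sig += q - 1
    return s * per_sig + s * n


def bic(loglik: float, k: int, n_obs: int) -> float:
    """log(n) * k - 2 * log L, with n the total number of counted mutations."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return float(np.log(n_obs) * k - 2.0 * loglik)


# ---------------------------------------------------------------------------
# fused likelihood-gradient kernel


@njit(fastmath=True, cache=True)
def _nb_grad_fused(tflat, e_ns, c, tau, d_t, d_e_ns, want_loss):  # pragma: no cover
    """Gradient of the NB log-likelihood through mu = T x E.

    tflat: (D, s) flattened signature tensor; e_ns: (n, s) exposures in
    sample-major layout; c: (D, n) counts.  Writes dL/dT into d_t and
    dL/dE into d_e_ns; returns the mu-dependent part of the
    log-likelihood when want_loss is true.
    """
    D, s = tflat.shape
    n = e_ns.shape[0]
    d_t[:] = 0.0
    d_e_ns[:] = 0.0
    loss = 0.0
    for i in range(D):
        for j in range(n):
            mu = MU_FLOOR
            for k in range(s):
                mu += tflat[i, k] * e_ns[j, k]
            cij = c[i, j]
            g = cij / mu - (cij + tau) / (tau + mu)
            for k in range(s):
                d_t[i, k] += g * e_ns[j, k]
                d_e_ns[j, k] += g * tflat[i, k]
            if want_loss:
                loss += tau * (np.log(tau) - np.log(tau + mu)) + cij * (
                    np.log(mu) - np.log(tau + mu)
                )
    return loss


# ---------------------------------------------------------------------------
# unconstrained parametrisation


def _softmax(z: np.ndarray, axis: int) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def params_to_model(
    params: dict[str, np.ndarray],
) -> tuple[CoreSpectra, TensorFactors, ExposureMatrix]:
    """Map free parameters to the constrained model quantities."""
    core = CoreSpectra(_softmax(params["z0"], axis=2))
    ones = np.ones((1, params["beta_t"].size))
    factors = TensorFactors(
        b_t=np.exp(params["beta_t"]),
        b_r=np.exp(params["beta_r"]),
        a_t=np.exp(params["alpha_t"]),
        a_r=np.exp(params["alpha_r"]),
        m=1.0 / (1.0 + np.exp(-params["xi"])),
        k_epi=np.vstack([ones, np.exp(params["kappa_epi"])]),
        k_nuc=np.vstack([ones, np.exp(params["kappa_nuc"])]),
        k_clu=np.vstack([ones, np.exp(params["kappa_clu"])]),
        s0=_softmax(params["z_s0"], axis=0),
    )
    return core, factors, ExposureMatrix(np.exp(params["eta"]))


def model_to_params(
    core: CoreSpectra, factors: TensorFactors, exposures: ExposureMatrix
) -> dict[str, np.ndarray]:
    """Inverse map (up to softmax shift); used to warm-start refits."""
    eps = 1e-12
    m = np.clip(factors.m, 1e-9, 1 - 1e-9)
    return {
        "z0": np.log(core.t0 + eps),
        "beta_t": np.log(factors.b_t),
        "beta_r": np.log(factors.b_r),
        "alpha_t": np.log(factors.a_t),
        "alpha_r": np.log(factors.a_r),
        "xi": np.log(m / (1 - m)),
        "kappa_epi": np.log(factors.k_epi[1:]),
        "kappa_nuc": np.log(factors.k_nuc[1:]),
        "kappa_clu": np.log(factors.k_clu[1:]),
        "z_s0": np.log(factors.s0 + eps),
        "eta": np.log(exposures.e + eps),
    }


def _truncated_normal(rng, shape, scale=0.1):
    return np.clip(rng.normal(0.0, scale, shape), -2 * scale, 2 * scale)


def init_params(
    rng: np.random.Generator,
    s: int,
    p: int,
    q: int,
    n: int,
    state_sizes: tuple[int, int, int],
    sample_totals: np.ndarray,
    snv_fraction: float,
) -> dict[str, np.ndarray]:
    """Random initialisation on the free scale.

    Spectra and scalar factors start near uniform/neutral (truncated
    normal noise).  Exposures start at the scale that reproduces each
    sample's observed total under the initial tensor mass — without this
    the first epochs are spent matching orders of magnitude.
    """
    te, tn, tc = state_sizes
    xi0 = np.log(snv_fraction / max(1e-6, 1.0 - snv_fraction)) if 0 < snv_fraction < 1 else 2.0
    params = {
        "z0": _truncated_normal(rng, (2, 2, p, s)),
        "beta_t": _truncated_normal(rng, s),
        "beta_r": _truncated_normal(rng, s),
        "alpha_t": _truncated_normal(rng, s),
        "alpha_r": _truncated_normal(rng, s),
        "xi": xi0 + _truncated_normal(rng, s),
        "kappa_epi": _truncated_normal(rng, (te - 1, s)),
        "kappa_nuc": _truncated_normal(rng, (tn - 1, s)),
        "kappa_clu": _truncated_normal(rng, (tc - 1, s)),
        "z_s0": _truncated_normal(rng, (q, s)) if q else np.zeros((0, s)),
        "eta": np.zeros((s, n)),
    }
    core, factors, _ = params_to_model(params)
    t = assemble_signature_tensor(core, factors)
    mass = t.t.reshape(-1, s).sum(axis=0)
    if q:
        mass = mass + (factors.s0 * (1 - factors.m)).sum(axis=0)
    eta = np.log(np.maximum(sample_totals, 1.0) / (s * mass)[:, None])
    params["eta"] = eta + _truncated_normal(rng, (s, n))
    return params


# ---------------------------------------------------------------------------
# analytic gradient


def _forward_backward(
    params: dict[str, np.ndarray],
    c_flat: np.ndarray,  # (D, n) float64 SNV counts
    c_oth: np.ndarray,  # (q, n)
    tau: float,
    shape_states: tuple[int, int, int],
    p: int,
    buffers: dict[str, np.ndarray],
    want_loss: bool,
) -> tuple[float, dict[str, np.ndarray]]:
    """Log-likelihood (mu-dependent part) and its gradient on the free scale."""
    core, factors, exposures = params_to_model(params)
    s = factors.rank
    te, tn, tc = shape_states
    n = exposures.e.shape[1]
    q = c_oth.shape[0]

    t = assemble_signature_tensor(core, factors).t  # (3,3,te,tn,tc,p,s)
    tflat = np.ascontiguousarray(t.reshape(-1, s))
    e_ns = np.ascontiguousarray(exposures.e.T)  # (n, s)

    d_tflat = buffers["d_tflat"]
    d_e_ns = buffers["d_e_ns"]
    loss = _nb_grad_fused(tflat, e_ns, c_flat, tau, d_tflat, d_e_ns, want_loss)

    # other-mutation block (small, plain numpy)
    d_e = d_e_ns.T.copy()  # (s, n)
    d_m_other = np.zeros(s)
    d_s0 = np.zeros((q, s))
    if q:
        ssig = factors.s0 * (1.0 - factors.m)[None, :]  # (q, s)
        mu_oth = np.maximum(ssig @ exposures.e, MU_FLOOR)
        g_oth = c_oth / mu_oth - (c_oth + tau) / (tau + mu_oth)
        if want_loss:
            loss += float(
                (tau * (np.log(tau) - np.log(tau + mu_oth))
                 + c_oth * (np.log(mu_oth) - np.log(tau + mu_oth))).sum()
            )
        d_ssig = g_oth @ exposures.e.T  # (q, s)
        d_e += ssig.T @ g_oth
        d_s0 = d_ssig * (1.0 - factors.m)[None, :]
        d_m_other = -(d_ssig * factors.s0).sum(axis=0)

    # backprop through the multiplicative tensor assembly
    w = d_tflat.reshape(t.shape)  # dL/dT
    pw = w * t  # dL/dlog(factor) mass per cell
    grads: dict[str, np.ndarray] = {}

    q_ij = pw.sum(axis=(2, 3, 4, 5))  # (3, 3, s)
    grads["beta_t"] = np.einsum("i,ijs->s", _BIAS_EXP, q_ij)
    grads["beta_r"] = np.einsum("j,ijs->s", _BIAS_EXP, q_ij)
    grads["alpha_t"] = np.einsum("i,ijs->s", _ACT_EXP, q_ij)
    grads["alpha_r"] = np.einsum("j,ijs->s", _ACT_EXP, q_ij)

    d_m = q_ij.sum(axis=(0, 1)) / factors.m + d_m_other
    grads["xi"] = d_m * factors.m * (1.0 - factors.m)

    grads["kappa_epi"] = pw.sum(axis=(0, 1, 3, 4, 5))[1:]
    grads["kappa_nuc"] = pw.sum(axis=(0, 1, 2, 4, 5))[1:]
    grads["kappa_clu"] = pw.sum(axis=(0, 1, 2, 3, 5))[1:]

    # dL/dT1: contract the state axes against the k-product, scale by b*a*m
    kprod = (
        factors.k_epi[:, None, None, :]
        * factors.k_nuc[None, :, None, :]
        * factors.k_clu[None, None, :, :]
    )  # (te, tn, tc, s)
    wk = np.einsum("ijabcps,abcs->ijps", w, kprod)
    g1 = (
        (factors.b_t[None, :] ** _BIAS_EXP[:, None])[:, None, :]
        * (factors.b_r[None, :] ** _BIAS_EXP[:, None])[None, :, :]
        * (factors.a_t[None, :] ** _ACT_EXP[:, None])[:, None, :]
        * (factors.a_r[None, :] ** _ACT_EXP[:, None])[None, :, :]
        * factors.m[None, None, :]
    )  # (3, 3, s)
    d_t1 = wk * g1[:, :, None, :]  # (3, 3, p, s)

    # linear map T1 <- T0 blocks, transposed
    d_cl = d_t1[0, 0] + 0.5 * (d_t1[0, 2] + d_t1[2, 0]) + 0.25 * d_t1[2, 2]
    d_cg = d_t1[0, 1] + 0.5 * (d_t1[0, 2] + d_t1[2, 1]) + 0.25 * d_t1[2, 2]
    d_tl = d_t1[1, 0] + 0.5 * (d_t1[1, 2] + d_t1[2, 0]) + 0.25 * d_t1[2, 2]
    d_tg = d_t1[1, 1] + 0.5 * (d_t1[1, 2] + d_t1[2, 1]) + 0.25 * d_t1[2, 2]
    d_t0 = np.empty_like(core.t0)
    d_t0[0, 0], d_t0[0, 1], d_t0[1, 0], d_t0[1, 1] = d_cl, d_cg, d_tl, d_tg
    # softmax backprop per (strand pair, signature), over the channel axis
    inner = (d_t0 * core.t0).sum(axis=2, keepdims=True)
    grads["z0"] = core.t0 * (d_t0 - inner)

    if q:
        inner0 = (d_s0 * factors.s0).sum(axis=0, keepdims=True)
        grads["z_s0"] = factors.s0 * (d_s0 - inner0)
    else:
        grads["z_s0"] = np.zeros((0, s))

    grads["eta"] = d_e * exposures.e
    return loss, grads


# ---------------------------------------------------------------------------
# Adam ascent


def _adam_fit(
    params: dict[str, np.ndarray],
    c_flat: np.ndarray,
    c_oth: np.ndarray,
    tau: float,
    config: FitConfig,
    shape_states: tuple[int, int, int],
    p: int,
) -> tuple[dict[str, np.ndarray], list[tuple[int, float]], float]:
    """Maximise the log-likelihood from a given starting point.

    Returns (params, trace, final mu-dependent log-likelihood).  Raises
    FloatingPointError on a non-finite loss so callers can retry.
    """
    n = c_flat.shape[1]
    s = config.rank
    d = 9 * int(np.prod(shape_states)) * p
    buffers = {
        "d_tflat": np.empty((d, s)),
        "d_e_ns": np.empty((n, s)),
    }
    m1 = {k: np.zeros_like(v) for k, v in params.items()}
    m2 = {k: np.zeros_like(v) for k, v in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    decay = (config.lr_final / config.lr) ** (1.0 / max(1, config.epochs - 1))
    trace: list[tuple[int, float]] = []
    loss = np.nan
    for epoch in range(config.epochs):
        want = (epoch % config.trace_every == 0) or (epoch == config.epochs - 1)
        loss, grads = _forward_backward(
            params, c_flat, c_oth, tau, shape_states, p, buffers, want
        )
        if want:
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            trace.append((epoch, -loss))  # store as a (negative log-lik) loss
        lr = config.lr * decay**epoch
        t_adam = epoch + 1
        for key, g in grads.items():
            if g.size == 0:
                continue
            m1[key] = b1 * m1[key] + (1 - b1) * g
            m2[key] = b2 * m2[key] + (1 - b2) * g * g
            mhat = m1[key] / (1 - b1**t_adam)
            vhat = m2[key] / (1 - b2**t_adam)
            params[key] = params[key] + lr * mhat / (np.sqrt(vhat) + eps)
    return params, trace, float(loss)


# ---------------------------------------------------------------------------
# public fitting API


def _as_arrays(
    c_snv: CountTensor | np.ndarray, c_other: OtherCountMatrix | np.ndarray | None
):
    snv = c_snv.counts if isinstance(c_snv, CountTensor) else np.asarray(c_snv)
    if c_other is None:
        oth = np.zeros((0, snv.shape[-1]))
    elif isinstance(c_other, OtherCountMatrix):
        oth = c_other.counts
    else:
        oth = np.asarray(c_other)
    return snv, oth


def fit(
    c_snv: CountTensor | np.ndarray,
    c_other: OtherCountMatrix | np.ndarray | None,
    config: FitConfig,
    init: dict[str, np.ndarray] | None = None,
) -> ModelFit:
    """Maximum-likelihood fit at a fixed rank, best of ``n_init`` restarts.

    ``c_snv`` is the 7-D SNV count tensor, ``c_other`` the category
    matrix (may be None).  ``init`` warm-starts from given free
    parameters and skips the random restarts (used by the bootstrap).
    A non-finite loss triggers a retry at half the learning rate.
    """
    snv, oth = _as_arrays(c_snv, c_other)
    if oth.size and oth.shape[-1] != snv.shape[-1]:
        raise ValueError("SNV tensor and other matrix must share the sample axis")
    shape_states = snv.shape[2:5]
    p = snv.shape[5]
    n = snv.shape[-1]
    q = oth.shape[0]
    s = config.rank
    c_flat = np.ascontiguousarray(snv.reshape(-1, n).astype(np.float64))
    c_oth = np.ascontiguousarray(oth.astype(np.float64))
    sample_totals = c_flat.sum(axis=0) + c_oth.sum(axis=0)
    total = float(sample_totals.sum())
    snv_fraction = float(c_flat.sum() / total) if total else 0.9

    starts: list[dict[str, np.ndarray]]
    if init is not None:
        starts = [init]
    else:
        root = np.random.default_rng(config.seed)
        starts = [
            init_params(
                np.random.default_rng(root.integers(2**31)),
                s, p, q, n, shape_states, sample_totals, snv_fraction,
            )
            for _ in range(config.n_init)
        ]

    best = None
    for i, start in enumerate(starts):
        cfg = config
        attempt = {k: v.copy() for k, v in start.items()}
        for retry in range(config.max_retries + 1):
            try:
                fitted, trace, ll_part = _adam_fit(
                    attempt, c_flat, c_oth, config.tau, cfg, shape_states, p
                )
                break
            except FloatingPointError:
                if retry == config.max_retries:
                    raise
                cfg = replace(cfg, lr=cfg.lr / 2)
                attempt = {k: v.copy() for k, v in start.items()}
                log.warning("restarting init %d at lr=%g", i, cfg.lr)
        if best is None or ll_part > best[2]:
            best = (fitted, trace, ll_part)

    fitted, trace, _ = best
    core, factors, exposures = params_to_model(fitted)
    t = assemble_signature_tensor(core, factors)
    mu_snv, mu_oth = expected_counts(t, factors.s0, factors.m, exposures)
    loglik = nb_loglik(
        snv, mu_snv, c_oth if q else None, mu_oth if q else None, config.tau
    )
    k = parameter_count(s, p, q, n, shape_states)
    n_obs = int(round(total))
    return ModelFit(
        core=core,
        factors=factors,
        exposures=exposures,
        tau=config.tau,
        loglik=loglik,
        bic=bic(loglik, k, max(n_obs, 1)),
        config=config,
        trace=trace,
        n_parameters=k,
        n_observations=n_obs,
    )


def rank_scan(
    c_snv: CountTensor | np.ndarray,
    c_other: OtherCountMatrix | np.ndarray | None,
    ranks: list[int],
    config: FitConfig,
) -> RankScan:
    """Fit every candidate rank and tabulate BICs."""
    if not ranks:
        raise ValueError("ranks must be non-empty")
    fits = [fit(c_snv, c_other, replace(config, rank=s)) for s in ranks]
    return RankScan(fits)
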