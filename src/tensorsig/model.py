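"""The signature tensor model and its negative-binomial likelihood.

A tensor signature is defined by four strand-resolved 96-channel spectra
(coding/template x leading/lagging), two strand-bias scalars ``b_t`` and
``b_r``, two regional amplitudes ``a_t`` and ``a_r``, an SNV fraction
``m``, per-state activity scalars ``k`` for the epigenome, nucleosome and
clustering axes (baseline state fixed at 1), and a spectrum ``S0`` over
the non-SNV categories.  These low-dimensional factors are broadcast and
multiplied into the full signature tensor

    T = T1 (.) B (.) A (.) M (.) K_epi (.) K_nuc (.) K_clu

of shape (3, 3, n_epi, n_nuc, 2, 96, s).  Expected counts are the inner
product of T (and of S0 scaled by 1 - m) with the exposure matrix E, and
observed counts are modelled as negative binomial with dispersion tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

MU_FLOOR = 1e-10  # guards log(mu) when expected counts underflow

#: transcription-axis exponents of b_t / a_t (coding, template, unknown) and
#: replication-axis exponents of b_r / a_r (leading, lagging, unknown)
_BIAS_EXPONENTS = np.array([1.0, -1.0, 0.0])
_ACTIVITY_EXPONENTS = np.array([1.0, 1.0, 0.0])


def broadcast_multiply(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Element-wise product after aligning trailing axes.

    Size-1 axes are expanded; a mismatch on any non-singleton axis is an
    error (e.g. a 2x2 array cannot combine with a 1x1x3 array, while
    2x2x1 with 1x1x3 gives 2x2x3).
    """
    x, y = np.asarray(x), np.asarray(y)
    for ax, (a, b) in enumerate(zip(x.shape[::-1], y.shape[::-1])):
        if a != b and 1 not in (a, b):
            raise ValueError(
                f"shapes {x.shape} and {y.shape} incompatible on trailing axis {ax}"
            )
    return x * y


@dataclass
class CoreSpectra:
    """The four strand-specific normalised spectra per signature.

    ``t0`` has shape (2, 2, p, s): axis 0 is transcription (coding,
    template), axis 1 replication (leading, lagging), and each 96-vector
    sums to one for every (strand pair, signature).
    """

    t0: np.ndarray

    def __post_init__(self) -> None:
        self.t0 = np.asarray(self.t0, dtype=float)
        if self.t0.ndim != 4 or self.t0.shape[:2] != (2, 2):
            raise ValueError(f"t0 must be (2, 2, p, s), got {self.t0.shape}")
        if np.any(self.t0 < 0):
            raise ValueError("core spectra must be non-negative")
        sums = self.t0.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each strand-specific spectrum must sum to 1")

    @property
    def n_channels(self) -> int:
        return self.t0.shape[2]

    @property
    def rank(self) -> int:
        return self.t0.shape[3]


@dataclass
class TensorFactors:
    """Scalar/vector factors of each signature (see module docstring)."""

    b_t: np.ndarray  # (s,) transcriptional strand bias
    b_r: np.ndarray  # (s,) replicational strand bias
    a_t: np.ndarray  # (s,) transcribed vs untranscribed amplitude
    a_r: np.ndarray  # (s,) early vs late replicating amplitude
    m: np.ndarray  # (s,) SNV fraction in [0, 1]
    k_epi: np.ndarray  # (n_epi, s), first row == 1
    k_nuc: np.ndarray  # (n_nuc, s), first row == 1
    k_clu: np.ndarray  # (2, s), first row == 1
    s0: np.ndarray  # (q, s) other-type spectra, columns sum to 1

    def __post_init__(self) -> None:
        s = len(self.b_t)
        for name in ("b_t", "b_r", "a_t", "a_r", "m"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (s,):
                raise ValueError(f"{name} must have shape ({s},)")
        for name in ("b_t", "b_r", "a_t", "a_r"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if np.any(self.m < 0) or np.any(self.m > 1):
            raise ValueError("m must lie in [0, 1]")
        for name in ("k_epi", "k_nuc", "k_clu"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.ndim != 2 or arr.shape[1] != s:
                raise ValueError(f"{name} must be (states, {s})")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
            if not np.allclose(arr[0], 1.0):
                raise ValueError(f"baseline (first) row of {name} must be 1")
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.s0.ndim != 2 or self.s0.shape[1] != s:
            raise ValueError(f"s0 must be (q, {s})")
        if np.any(self.s0 < 0):
            raise ValueError("s0 must be non-negative")

    @property
    def rank(self) -> int:
        return len(self.b_t)

    @property
    def state_sizes(self) -> tuple[int, int, int]:
        return (self.k_epi.shape[0], self.k_nuc.shape[0], self.k_clu.shape[0])


@dataclass
class ExposureMatrix:
    """Non-negative signature-by-sample exposures (s, n)."""

    e: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        if self.e.ndim != 2:
            raise ValueError("exposures must be 2-D (signatures x samples)")
        if np.any(self.e < 0):
            raise ValueError("exposures must be non-negative")


@dataclass(frozen=True)
class Dispersion:
    """Negative-binomial dispersion; tau -> infinity recovers Poisson."""

    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")


@dataclass
class SignatureTensor:
    """The fully assembled tensor (3, 3, n_epi, n_nuc, 2, p, s)."""

    t: np.ndarray

    def __post_init__(self) -> None:
        if self.t.ndim != 7 or self.t.shape[:2] != (3, 3):
            raise ValueError(f"expected 7-D (3, 3, ...) tensor, got {self.t.shape}")
        if np.any(self.t < 0):
            raise ValueError("signature tensor must be non-negative")

    @property
    def rank(self) -> int:
        return self.t.shape[-1]


# ---------------------------------------------------------------------------
# assembly


def stack_t1(core: CoreSpectra) -> np.ndarray:
    """Stack the 2x2 core spectra into the 3x3 layout with unknown strands.

    The third row/column holds the mean over the unresolved strand, and
    the (3, 3) block the grand mean over all four spectra.
    """
    cl, cg = core.t0[0, 0], core.t0[0, 1]
    tl, tg = core.t0[1, 0], core.t0[1, 1]
    p, s = cl.shape
    t1 = np.empty((3, 3, p, s))
    t1[0, 0], t1[0, 1], t1[0, 2] = cl, cg, 0.5 * (cl + cg)
    t1[1, 0], t1[1, 1], t1[1, 2] = tl, tg, 0.5 * (tl + tg)
    t1[2, 0], t1[2, 1] = 0.5 * (cl + tl), 0.5 * (cg + tg)
    t1[2, 2] = 0.25 * (cl + cg + tl + tg)
    return t1


def bias_tensor(b_t: np.ndarray, b_r: np.ndarray) -> np.ndarray:
    """Strand-bias factor B of shape (3, 3, 1, s).

    Rows follow the transcription axis (coding, template, unknown) with
    exponents (+1, -1, 0) on b_t; columns follow the replication axis
    (leading, lagging, unknown) with the same exponents on b_r.  Values
    above 1 shift mass towards the coding / leading strand.
    """
    b_t, b_r = np.asarray(b_t, float), np.asarray(b_r, float)
    if np.any(b_t <= 0) or np.any(b_r <= 0):
        raise ValueError("strand biases must be strictly positive")
    out = (
        b_t[None, :] ** _BIAS_EXPONENTS[:, None]
    )[:, None, :] * (b_r[None, :] ** _BIAS_EXPONENTS[:, None])[None, :, :]
    return out[:, :, None, :]


def activity_tensor(a_t: np.ndarray, a_r: np.ndarray) -> np.ndarray:
    """Regional-activity factor A of shape (3, 3, 1, s).

    a_t multiplies every transcribed (oriented) row, a_r every oriented
    replication column; the fully unoriented (3, 3) entry is 1.
    """
    a_t, a_r = np.asarray(a_t, float), np.asarray(a_r, float)
    if np.any(a_t <= 0) or np.any(a_r <= 0):
        raise ValueError("amplitudes must be strictly positive")
    out = (
        a_t[None, :] ** _ACTIVITY_EXPONENTS[:, None]
    )[:, None, :] * (a_r[None, :] ** _ACTIVITY_EXPONENTS[:, None])[None, :, :]
    return out[:, :, None, :]


def assemble_signature_tensor(
    core: CoreSpectra, factors: TensorFactors
) -> SignatureTensor:
    """Broadcast all factors into the full signature tensor.

    T[i, j, e, u, c, :, s] = T1[i, j, :, s] * B[i, j, s] * A[i, j, s]
                             * m[s] * k_epi[e, s] * k_nuc[u, s] * k_clu[c, s]
    """
    t1 = stack_t1(core)  # (3, 3, p, s)
    b = bias_tensor(factors.b_t, factors.b_r)[:, :, 0, :]  # (3, 3, s)
    a = activity_tensor(factors.a_t, factors.a_r)[:, :, 0, :]
    strand = t1 * (b * a)[:, :, None, :] * factors.m[None, None, None, :]
    # introduce the three state axes as singletons, then broadcast each k
    t = strand[:, :, None, None, None, :, :]
    t = broadcast_multiply(t, factors.k_epi[:, None, None, None, :])
    t = broadcast_multiply(t, factors.k_nuc[:, None, None, :])
    t = broadcast_multiply(t, factors.k_clu[:, None, :])
    return SignatureTensor(t)


def expected_counts(
    t: SignatureTensor,
    s0: np.ndarray,
    m: np.ndarray,
    e: ExposureMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected SNV tensor and other matrix under the model.

    mu_snv = T x E (inner product over signatures), and
    mu_other = (S0 * (1 - m)) x E.
    """
    mu_snv = np.tensordot(t.t, e.e, axes=([6], [0]))
    mu_other = (s0 * (1.0 - m)[None, :]) @ e.e
    return mu_snv, mu_other


# ---------------------------------------------------------------------------
# likelihood


def nb_logpmf(c: np.ndarray, mu: np.ndarray, tau: float) -> np.ndarray:
    """Element-wise negative-binomial log PMF with mean mu, dispersion tau."""
    c = np.asarray(c, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), MU_FLOOR)
    if np.any(~np.isfinite(mu)) or np.any(mu < 0):
        raise ValueError("expectations must be finite and non-negative")
    return (
        gammaln(tau + c)
        - gammaln(tau)
        - gammaln(c + 1.0)
        + tau * (np.log(tau) - np.log(tau + mu))
        + c * (np.log(mu) - np.log(tau + mu))
    )


def nb_loglik(
    c_snv: np.ndarray,
    mu_snv: np.ndarray,
    c_other: np.ndarray | None,
    mu_other: np.ndarray | None,
    tau: float,
) -> float:
    """Total log-likelihood: SNV term plus other-mutation term."""
    total = float(nb_logpmf(c_snv, mu_snv, tau).sum())
    if c_other is not None and c_other.size:
        total += float(nb_logpmf(c_other, mu_other, tau).sum())
    return total


def signature_posterior(
    t: SignatureTensor,
    e: ExposureMatrix,
    channel: int,
    states: tuple[int, int, int, int, int],
    sample: int,
) -> tuple[np.ndarray, bool]:
    """Posterior probability of each signature for one tensor cell.

    Proportional to T[states, channel, s] * E[s, sample].  If every
    signature has zero intensity at the cell the posterior is undefined;
    a uniform distribution is returned with ``degenerate=True``.
    """
    i, j, ei, u, cl = states
    intensity = t.t[i, j, ei, u, cl, channel, :] * e.e[:, sample]
    total = intensity.sum()
    if total <= 0:
        s = t.rank
        return np.full(s, 1.0 / s), True
    return intensity / total, False
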