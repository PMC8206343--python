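"""Bootstrap confidence intervals for fitted tensor-signature parameters.

Each replicate refits the model on a random two-thirds subset of samples,
warm-started at the reference MLE with a random 10% of the free
parameters perturbed.  Refitted signatures are matched back to the
reference by optimal cosine-distance assignment; replicates whose
matched signature tensors deviate from the reference by a total
variation distance of 0.2 or more are rejected.  Confidence intervals
are percentiles over the accepted replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .catalogue import CountTensor, OtherCountMatrix
from .inference import FitConfig, ModelFit, fit, model_to_params
from .model import ExposureMatrix, assemble_signature_tensor

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 300
    subsample_fraction: float = 2.0 / 3.0
    perturbation_fraction: float = 0.10
    perturbation_scale: float = 0.10  # sd of the log-multiplicative noise
    acceptance_threshold: float = 0.2
    percentiles: tuple[float, float] = (5.0, 95.0)
    epoch_fraction: float = 0.1  # replicate refit budget vs the main fit
    seed: int = 0
    tv_aggregate: str = "max"  # or "mean" over signatures

    def __post_init__(self) -> None:
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must be in (0, 1)")
        if self.acceptance_threshold <= 0:
            raise ValueError("acceptance_threshold must be positive")


@dataclass
class BootstrapResult:
    """Accepted replicates and per-parameter percentile intervals.

    ``intervals`` maps a parameter name (b_t, b_r, a_t, a_r, m, k_epi,
    k_nuc, k_clu, s0, spectra) to a (2, ...) array of lower/upper
    bounds.  The bootstrap distribution may exclude the MLE, so only
    lower <= upper is guaranteed.
    """

    replicates: dict[str, list[np.ndarray]] = field(default_factory=dict)
    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    distances: list[float] = field(default_factory=list)
    n_accepted: int = 0
    n_total: int = 0

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_total if self.n_total else float("nan")


# ---------------------------------------------------------------------------
# signature matching and acceptance


def _flat_signatures(fit_: ModelFit) -> np.ndarray:
    """(s, D) matrix of flattened signature tensors."""
    t = assemble_signature_tensor(fit_.core, fit_.factors).t
    s = t.shape[-1]
    return t.reshape(-1, s).T


def match_signatures(candidate: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permutation aligning candidate signatures to the reference.

    Both arguments are (s, D) flattened signature matrices.  The optimal
    assignment minimising total cosine distance is returned as an array
    ``perm`` with ``candidate[perm[i]]`` matching ``reference[i]``.
    """
    if candidate.shape != reference.shape:
        raise ValueError("candidate and reference must have equal rank and size")
    norm_c = np.linalg.norm(candidate, axis=1, keepdims=True)
    norm_r = np.linalg.norm(reference, axis=1, keepdims=True)
    cosine = (reference / np.maximum(norm_r, 1e-300)) @ (
        candidate / np.maximum(norm_c, 1e-300)
    ).T
    rows, cols = linear_sum_assignment(1.0 - cosine)
    return cols[np.argsort(rows)]


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Half the L1 distance between two probability-normalised vectors."""
    p = p / p.sum()
    q = q / q.sum()
    return 0.5 * float(np.abs(p - q).sum())


def accept_replicate(
    candidate: np.ndarray,
    reference: np.ndarray,
    threshold: float = 0.2,
    aggregate: str = "max",
) -> tuple[bool, float]:
    """Accept iff the signature-wise TV distance stays below threshold.

    Inputs are matched (s, D) flattened signature matrices; each row is
    normalised to a probability vector before the comparison.  The
    per-signature distances are aggregated by max (default) or mean.
    """
    dists = [total_variation(c, r) for c, r in zip(candidate, reference)]
    distance = float(np.max(dists) if aggregate == "max" else np.mean(dists))
    return distance < threshold, distance


# ---------------------------------------------------------------------------
# the bootstrap loop


_VECTOR_PARAMS = ("b_t", "b_r", "a_t", "a_r", "m")
_MATRIX_PARAMS = ("k_epi", "k_nuc", "k_clu", "s0")


def _perturb(params: dict[str, np.ndarray], rng, fraction: float, scale: float):
    """Multiply a random subset of free parameters by exp(N(0, scale^2))."""
    sizes = {k: v.size for k, v in params.items()}
    total = sum(sizes.values())
    n_pick = int(round(fraction * total))
    picks = rng.choice(total, size=n_pick, replace=False)
    flat_offset = 0
    out = {}
    for key, v in params.items():
        sel = picks[(picks >= flat_offset) & (picks < flat_offset + v.size)] - flat_offset
        w = v.copy()
        if sel.size:
            noise = rng.normal(0.0, scale, sel.size)
            w.flat[sel] = w.flat[sel] + noise  # additive on the free (log) scale
        out[key] = w
        flat_offset += v.size
    return out


def bootstrap_fit(
    reference: ModelFit,
    c_snv: CountTensor | np.ndarray,
    c_other: OtherCountMatrix | np.ndarray | None,
    config: BootstrapConfig,
) -> BootstrapResult:
    """Bootstrap CIs for all signature parameters of a fitted model."""
    snv = c_snv.counts if isinstance(c_snv, CountTensor) else np.asarray(c_snv)
    oth = None
    if c_other is not None:
        oth = c_other.counts if isinstance(c_other, OtherCountMatrix) else np.asarray(c_other)
    n = snv.shape[-1]
    n_sub = int(np.ceil(config.subsample_fraction * n))
    rng = np.random.default_rng(config.seed)
    ref_flat = _flat_signatures(reference)
    ref_params = model_to_params(
        reference.core, reference.factors, reference.exposures
    )
    epochs = max(1, int(reference.config.epochs * config.epoch_fraction))
    refit_cfg = replace(reference.config, epochs=epochs, n_init=1)

    result = BootstrapResult(
        replicates={k: [] for k in _VECTOR_PARAMS + _MATRIX_PARAMS + ("spectra",)}
    )
    result.n_total = config.n_replicates
    for rep in range(config.n_replicates):
        keep = np.sort(rng.choice(n, size=n_sub, replace=False))
        start = _perturb(
            ref_params, rng, config.perturbation_fraction, config.perturbation_scale
        )
        start["eta"] = start["eta"][:, keep]
        sub_snv = np.ascontiguousarray(snv[..., keep])
        sub_oth = np.ascontiguousarray(oth[:, keep]) if oth is not None else None
        try:
            refit = fit(sub_snv, sub_oth, refit_cfg, init=start)
        except FloatingPointError:
            log.warning("bootstrap replicate %d diverged; counted as rejected", rep)
            continue
        cand_flat = _flat_signatures(refit)
        perm = match_signatures(cand_flat, ref_flat)
        ok, dist = accept_replicate(
            cand_flat[perm], ref_flat, config.acceptance_threshold, config.tv_aggregate
        )
        result.distances.append(dist)
        if not ok:
            continue
        result.n_accepted += 1
        f = refit.factors
        for key in _VECTOR_PARAMS:
            result.replicates[key].append(getattr(f, key)[perm])
        for key in _MATRIX_PARAMS:
            result.replicates[key].append(getattr(f, key)[:, perm])
        result.replicates["spectra"].append(refit.core.t0[..., perm])

    lo, hi = config.percentiles
    for key, values in result.replicates.items():
        if values:
            stack = np.stack(values)
            result.intervals[key] = np.percentile(stack, [lo, hi], axis=0)
    if result.n_total and result.acceptance_rate < 0.10:
        log.warning(
            "bootstrap acceptance rate %.1f%% is below 10%%; intervals may be unstable",
            100 * result.acceptance_rate,
        )
    return result
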