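"""Kataegis calling: a two-state HMM on inter-mutation distances.

Consecutive SNVs on a chromosome emit their distance in bp.  Clustered
stretches emit short, geometrically distributed distances (mean 100 bp);
unclustered stretches emit distances with the sample's genome-wide mean.
The most likely state path (Viterbi) labels every mutation clustered or
unclustered; maximal runs of clustered mutations form clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = 1e-12

CLUSTERED, UNCLUSTERED = 0, 1


@dataclass(frozen=True)
class HmmParameters:
    """Initial, transition and emission parameters of the two-state HMM.

    Defaults: a chain starts clustered with probability 0.01, stays in its
    state with probability 0.99, and clustered distances are geometric
    with success probability 1/100 (mean 100 bp).  The unclustered
    emission parameter is data-derived (reciprocal mean distance).
    """

    unclustered_geom_p: float
    initial_clustered: float = 0.01
    stay_prob: float = 0.99
    clustered_geom_p: float = 1.0 / 100.0

    def __post_init__(self) -> None:
        for name in ("unclustered_geom_p", "initial_clustered", "stay_prob",
                     "clustered_geom_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must lie strictly in (0, 1)")


@dataclass
class ClusterCall:
    """Per-variant clustered/unclustered labels plus cluster segments."""

    chrom: str
    sample_id: str
    positions: np.ndarray  # sorted variant positions (1-based)
    labels: np.ndarray  # bool, True = clustered, aligned with positions
    segments: pd.DataFrame = field(default=None)  # chrom,start,end,n_variants

    def __post_init__(self) -> None:
        if self.segments is None:
            self.segments = _segments_from_labels(
                self.chrom, self.positions, self.labels
            )


def intermutation_distances(positions: np.ndarray) -> np.ndarray:
    """Distances between consecutive sorted positions on one chromosome.

    Zero distances (same-position records) are collapsed to 1 bp, the
    smallest value in the geometric support.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    return np.maximum(np.diff(positions), 1)


def fit_unclustered_emission(distances: np.ndarray) -> float:
    """Geometric success probability = reciprocal mean distance.

    Clipped into (eps, 1 - eps) so degenerate inputs (all distances 1)
    keep the emission distribution proper.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("cannot fit emission parameter to zero distances")
    return float(np.clip(1.0 / distances.mean(), _EPS, 1.0 - _EPS))


def _log_geom_pmf(y: np.ndarray, p: float) -> np.ndarray:
    """log PMF of the geometric distribution on support {1, 2, ...}."""
    y = np.asarray(y, dtype=float)
    return np.log(p) + (y - 1.0) * np.log1p(-p)


def viterbi_states(distances: np.ndarray, params: HmmParameters) -> np.ndarray:
    """MAP state per distance emission, 0 = clustered, 1 = unclustered.

    Standard log-space Viterbi over the two-state chain.
    """
    y = np.asarray(distances, dtype=float)
    k = y.size
    if k == 0:
        return np.zeros(0, dtype=np.int64)
    log_emit = np.stack(
        [
            _log_geom_pmf(y, params.clustered_geom_p),
            _log_geom_pmf(y, params.unclustered_geom_p),
        ]
    )  # (2, k)
    log_init = np.log(
        [params.initial_clustered, 1.0 - params.initial_clustered]
    )
    stay, switch = np.log(params.stay_prob), np.log1p(-params.stay_prob)
    log_trans = np.array([[stay, switch], [switch, stay]])

    delta = np.empty((2, k))
    back = np.zeros((2, k), dtype=np.int64)
    delta[:, 0] = log_init + log_emit[:, 0]
    for t in range(1, k):
        scores = delta[:, t - 1][:, None] + log_trans  # (from, to)
        back[:, t] = np.argmax(scores, axis=0)
        delta[:, t] = np.max(scores, axis=0) + log_emit[:, t]
    states = np.empty(k, dtype=np.int64)
    states[-1] = int(np.argmax(delta[:, -1]))
    for t in range(k - 1, 0, -1):
        states[t - 1] = back[states[t], t]
    return states


def labels_from_states(states: np.ndarray, n_variants: int) -> np.ndarray:
    """Per-variant clustered flags from per-distance MAP states.

    A variant is clustered if either adjacent distance emission is in the
    clustered state, so a run of r clustered emissions yields r + 1
    clustered variants ("consecutive clustered mutations").  With fewer
    than two variants everything is unclustered.
    """
    labels = np.zeros(n_variants, dtype=bool)
    if n_variants < 2:
        return labels
    clustered = np.asarray(states) == CLUSTERED
    labels[:-1] |= clustered
    labels[1:] |= clustered
    return labels


def call_clusters(
    positions: np.ndarray,
    chrom: str = "chrom",
    sample_id: str = "sample",
    params: HmmParameters | None = None,
) -> ClusterCall:
    """End-to-end kataegis call for one (sample, chromosome).

    If ``params`` is None the unclustered emission parameter is fitted
    from these distances (callers doing per-sample fits across
    chromosomes should fit once and pass params explicitly).
    """
    positions = np.sort(np.asarray(positions, dtype=np.int64))
    if positions.size < 2:
        return ClusterCall(
            chrom, sample_id, positions, np.zeros(positions.size, dtype=bool)
        )
    dists = intermutation_distances(positions)
    if params is None:
        params = HmmParameters(unclustered_geom_p=fit_unclustered_emission(dists))
    states = viterbi_states(dists, params)
    return ClusterCall(
        chrom, sample_id, positions, labels_from_states(states, positions.size)
    )


def call_clusters_per_sample(
    variants: pd.DataFrame, params: HmmParameters | None = None
) -> list[ClusterCall]:
    """Kataegis calls for a table with columns sample_id, chrom, pos.

    The unclustered emission parameter is fitted per sample across all of
    its chromosomes (the genome-wide mutation rate is the scale-bearing
    unit), then states are decoded per chromosome.
    """
    calls = []
    for sid, svars in variants.groupby("sample_id", sort=False):
        if params is None:
            all_d = [
                intermutation_distances(np.sort(g["pos"].to_numpy(np.int64)))
                for _, g in svars.groupby("chrom", sort=False)
                if len(g) >= 2
            ]
            pooled = np.concatenate(all_d) if all_d else np.array([])
            if pooled.size == 0:
                sample_params = None
            else:
                sample_params = HmmParameters(
                    unclustered_geom_p=fit_unclustered_emission(pooled)
                )
        else:
            sample_params = params
        for chrom, g in svars.groupby("chrom", sort=False):
            calls.append(
                call_clusters(
                    g["pos"].to_numpy(np.int64), chrom, sid, sample_params
                )
            )
    return calls


def summarise_clusters(calls: list[ClusterCall]) -> pd.DataFrame:
    """One row per maximal clustered run: span in bp and variant count."""
    frames = [c.segments.assign(sample_id=c.sample_id) for c in calls]
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_variants", "length_bp", "sample_id"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out


def _segments_from_labels(
    chrom: str, positions: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    rows = []
    i = 0
    n = len(positions)
    while i < n:
        if labels[i]:
            j = i
            while j + 1 < n and labels[j + 1]:
                j += 1
            rows.append(
                (chrom, int(positions[i]), int(positions[j]), j - i + 1,
                 int(positions[j]) - int(positions[i]))
            )
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_variants", "length_bp"]
    )
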