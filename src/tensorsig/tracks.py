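"""Genomic state tracks and the rules that build them.

A :class:`StateTrack` is a labelled interval set over the genome (BED-style
0-based half-open coordinates) for one of the four state axes used by the
count tensor: transcription direction, replication direction, epigenetic
(ChromHMM consensus) state, or nucleosome position.  This module also
implements the derived tracks:

* replication direction from the slope of replication-timing profiles,
* the cross-cell-line ChromHMM consensus with its extra ``variable`` state,
* the nucleosome minor-in / minor-out / linker partition around dyads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

TX_LABELS = ("coding", "template", "unknown")
REP_LABELS = ("leading", "lagging", "unknown")
NUC_LABELS = ("none", "minor_in", "minor_out", "linker")
CLU_LABELS = ("unclustered", "clustered")

#: Roadmap 15-state ChromHMM mnemonics; ``variable`` marks consensus failure
#: and is the baseline state of the epigenome axis.
CHROMHMM_STATES = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)
EPI_LABELS = ("variable",) + CHROMHMM_STATES


@dataclass
class StateTrack:
    """Non-overlapping labelled intervals for one state axis.

    ``intervals`` is a DataFrame with columns ``chrom, start, end, label``
    (0-based half-open).  Lookups use binary search per chromosome, so
    intervals must not overlap within a chromosome.
    """

    intervals: pd.DataFrame
    axis_name: str
    label_set: tuple[str, ...]
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.intervals
        bad = set(df["label"]) - set(self.label_set)
        if bad:
            raise ValueError(f"labels {bad} not in label_set of axis {self.axis_name}")
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom} in {self.axis_name} track")
            self._index[chrom] = (starts, ends, grp["label"].to_numpy(object))

    def lookup(self, chrom: str, pos0: int, default: str | None = None) -> str | None:
        """Label covering 0-based position ``pos0``, or ``default``."""
        entry = self._index.get(chrom)
        if entry is None:
            return default
        starts, ends, labels = entry
        i = np.searchsorted(starts, pos0, side="right") - 1
        if i >= 0 and pos0 < ends[i]:
            return labels[i]
        return default


@dataclass
class GeneTrack:
    """Stranded gene intervals; may overlap (interval tree per chromosome)."""

    intervals: pd.DataFrame  # chrom, start, end, strand in {+,-}
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for chrom, grp in self.intervals.groupby("chrom", sort=False):
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), st)
                for s, e, st in zip(grp["start"], grp["end"], grp["strand"])
                if e > s
            )

    def strands_at(self, chrom: str, pos0: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos0)}


# ---------------------------------------------------------------------------
# replication direction from timing profiles


def build_replication_track(
    profiles: list[pd.DataFrame],
    bin_size: int | None = None,
) -> StateTrack:
    """Derive a leading/lagging orientation track from timing profiles.

    Each profile is a DataFrame ``chrom, start, end, value`` of binned
    replication timing on a shared grid.  Per bin, the slope of each
    profile is estimated by central finite differences; a bin is called
    ``rep(+)`` (rightward-replicating) if the mean slope across profiles
    is positive and its magnitude exceeds twice the standard deviation
    across profiles, ``rep(-)`` under the mirrored test, and ``*``
    otherwise.  A zero standard deviation passes the magnitude test
    whenever the mean is non-zero (the degenerate single-profile case).

    The returned track carries labels ``rep+ / rep- / *``.
    """
    if not profiles:
        raise ValueError("at least one replication-timing profile required")
    base = profiles[0][["chrom", "start", "end"]].reset_index(drop=True)
    values = np.stack(
        [p.sort_values(["chrom", "start"])["value"].to_numpy(float) for p in profiles]
    )  # (n_profiles, n_bins)
    rows = []
    chroms = base["chrom"].to_numpy(object)
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        v = values[:, mask]
        starts = base.loc[mask, "start"].to_numpy(np.int64)
        ends = base.loc[mask, "end"].to_numpy(np.int64)
        slopes = np.gradient(v, axis=1) if v.shape[1] > 1 else np.zeros_like(v)
        labels = classify_slopes(slopes)
        for s, e, lab in zip(starts, ends, labels):
            rows.append((chrom, s, e, lab))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return StateTrack(df, axis_name="replication", label_set=("rep+", "rep-", "*"))


def classify_slopes(slopes: np.ndarray) -> np.ndarray:
    """Vector of rep+/rep-/* calls from a (profiles x bins) slope array."""
    mean = slopes.mean(axis=0)
    sd = slopes.std(axis=0, ddof=0)
    confident = np.abs(mean) > 2.0 * sd
    # sd == 0 with a non-zero mean counts as confident (single profile or
    # perfectly agreeing profiles)
    confident |= (sd == 0) & (mean != 0)
    out = np.full(mean.shape, "*", dtype=object)
    out[confident & (mean > 0)] = "rep+"
    out[confident & (mean < 0)] = "rep-"
    return out


# ---------------------------------------------------------------------------
# ChromHMM consensus


def build_epigenome_consensus(
    tracks: list[StateTrack],
    agreement: float = 0.70,
    bin_size: int = 200,
) -> StateTrack:
    """Consensus ChromHMM state across cell lines.

    The genome (union of all track extents) is scanned in ``bin_size``
    windows; a window keeps the modal state if its frequency among cell
    lines with a call there is at least ``agreement``, and is labelled
    ``variable`` otherwise.  The output vocabulary is the 15 ChromHMM
    states plus ``variable`` (16 labels).
    """
    if not tracks:
        raise ValueError("no ChromHMM tracks given")
    if not 0 < agreement <= 1:
        raise ValueError("agreement must be in (0, 1]")
    chrom_extent: dict[str, int] = {}
    for t in tracks:
        for chrom, grp in t.intervals.groupby("chrom", sort=False):
            chrom_extent[chrom] = max(chrom_extent.get(chrom, 0), int(grp["end"].max()))
    rows = []
    for chrom, extent in chrom_extent.items():
        for start in range(0, extent, bin_size):
            mid = start + bin_size // 2
            calls = [t.lookup(chrom, mid) for t in tracks]
            calls = [c for c in calls if c is not None]
            label = consensus_label(calls, agreement)
            rows.append((chrom, start, min(start + bin_size, extent), label))
    df = _merge_adjacent(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))
    return StateTrack(df, axis_name="epigenome", label_set=EPI_LABELS)


def consensus_label(calls: list[str], agreement: float) -> str:
    """Modal state if its frequency reaches ``agreement``, else ``variable``."""
    if not calls:
        return "variable"
    counts = pd.Series(calls).value_counts()
    if counts.iloc[0] / len(calls) >= agreement:
        return str(counts.index[0])
    return "variable"


def _merge_adjacent(df: pd.DataFrame) -> pd.DataFrame:
    """Coalesce touching bins with identical labels."""
    if df.empty:
        return df
    out = []
    for (chrom, label), grp in df.groupby(["chrom", "label"], sort=False):
        grp = grp.sort_values("start")
        run_start = prev_end = None
        for s, e in zip(grp["start"], grp["end"]):
            if run_start is None:
                run_start, prev_end = s, e
            elif s == prev_end:
                prev_end = e
            else:
                out.append((chrom, run_start, prev_end, label))
                run_start, prev_end = s, e
        out.append((chrom, run_start, prev_end, label))
    return (
        pd.DataFrame(out, columns=["chrom", "start", "end", "label"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# nucleosome partition around dyads

# layout in distance from the dyad (0-based offset |pos - dyad|):
#   0..7      core flank, assigned to the dyad-adjacent minor-in label
#   8..57     ten alternating 5 bp stretches, minor-out first
#   58..115   linker (up to 58 bp)
#   >115      none
_CORE_FLANK = 7
_N_STRETCHES = 10
_STRETCH = 5
_LINKER = 58
NUCLEOSOME_REACH = _CORE_FLANK + _N_STRETCHES * _STRETCH + _LINKER  # 115


def nucleosome_label(offset: int) -> str:
    """Nucleosome-axis label for an absolute distance from the nearest dyad."""
    offset = abs(int(offset))
    if offset <= _CORE_FLANK:
        return "minor_in"
    k = (offset - _CORE_FLANK - 1) // _STRETCH
    if k < _N_STRETCHES:
        return "minor_out" if k % 2 == 0 else "minor_in"
    if offset <= NUCLEOSOME_REACH:
        return "linker"
    return "none"


class DyadTrack:
    """Sorted nucleosome dyad midpoints per chromosome (0-based)."""

    def __init__(self, dyads: pd.DataFrame):
        # dyads: chrom, pos (0-based midpoint)
        self._pos = {
            chrom: np.sort(grp["pos"].to_numpy(np.int64))
            for chrom, grp in dyads.groupby("chrom", sort=False)
        }

    def nucleosome_state(self, chrom: str, pos0: int) -> str:
        """minor_in / minor_out / linker relative to the nearest dyad."""
        positions = self._pos.get(chrom)
        if positions is None or len(positions) == 0:
            return "none"
        i = np.searchsorted(positions, pos0)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                d = abs(pos0 - int(positions[j]))
                if best is None or d < best:
                    best = d
        return nucleosome_label(best)
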