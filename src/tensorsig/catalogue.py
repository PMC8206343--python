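"""Variant annotation and count-tensor assembly.

Each accepted SNV is annotated with its 96-channel mutation type and five
genomic states (transcription, replication, epigenome, nucleosome,
clustering) and counted into a ``3 x 3 x 16 x 4 x 2 x 96 x n`` tensor;
MNVs, indels and SVs are tallied into a conventional category x sample
matrix.  The five state axes multiply out to 2 x 576 = 1152 state
combinations per trinucleotide channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .channels import (
    CHANNEL_LABELS,
    VariantRecord,
    VariantRejected,
    classify_other,
    classify_snv,
)
from .tracks import (
    CLU_LABELS,
    EPI_LABELS,
    NUC_LABELS,
    REP_LABELS,
    TX_LABELS,
    DyadTrack,
    GeneTrack,
    StateTrack,
)

log = logging.getLogger(__name__)

#: canonical axis order of the SNV count tensor
AXIS_NAMES = ("transcription", "replication", "epigenome", "nucleosome",
              "cluster", "channel", "sample")

DEFAULT_AXIS_LABELS = {
    "transcription": TX_LABELS,
    "replication": REP_LABELS,
    "epigenome": EPI_LABELS,
    "nucleosome": NUC_LABELS,
    "cluster": CLU_LABELS,
    "channel": CHANNEL_LABELS,
}


@dataclass(frozen=True)
class AnnotatedVariant:
    """An SNV (or other variant) with all tensor coordinates resolved."""

    variant: VariantRecord
    snv_channel: int | None  # 0..95, SNVs only
    tx_state: str = "unknown"
    rep_state: str = "unknown"
    epi_state: str = "variable"
    nuc_state: str = "none"
    clu_state: str = "unclustered"
    other_category: str | None = None  # non-SNVs only


@dataclass
class CountTensor:
    """SNV counts over (tx, rep, epi, nuc, clu, channel, sample)."""

    counts: np.ndarray
    axis_labels: dict[str, tuple[str, ...]]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        expected = tuple(len(self.axis_labels[a]) for a in AXIS_NAMES[:-1])
        expected += (len(self.sample_ids),)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_state_combinations(self) -> int:
        """Product of the five state-axis sizes (1152 at default labels)."""
        return int(np.prod(self.counts.shape[:5]))

    def per_sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=tuple(range(self.counts.ndim - 1)))

    def marginal(self, axis: str) -> np.ndarray:
        """Counts summed over every axis except ``axis`` and sample."""
        keep = AXIS_NAMES.index(axis)
        drop = tuple(i for i in range(len(AXIS_NAMES) - 1) if i != keep)
        return self.counts.sum(axis=drop)


@dataclass
class OtherCountMatrix:
    """MNV/indel/SV counts over (category, sample)."""

    counts: np.ndarray
    category_labels: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.category_labels)) != len(self.category_labels):
            raise ValueError("duplicate category labels")
        if self.counts.shape != (len(self.category_labels), len(self.sample_ids)):
            raise ValueError("counts shape does not match labels")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")


# ---------------------------------------------------------------------------
# per-variant state assignment


def assign_transcription_state(
    pyr_on_plus: bool, gene_strands: set[str]
) -> str:
    """Coding/template call from the strand of the mutated pyrimidine.

    The pyrimidine of the mutated pair sits on the + strand iff
    ``pyr_on_plus``; a gene on strand ``+`` has its coding (untranscribed)
    strand on ``+``.  Loci covered by genes of both directions, or by no
    gene, cannot be oriented and return ``unknown``.
    """
    if len(gene_strands) != 1:
        return "unknown"
    gene_strand = next(iter(gene_strands))
    pyr_strand = "+" if pyr_on_plus else "-"
    return "coding" if pyr_strand == gene_strand else "template"


def assign_replication_state(pyr_on_plus: bool, region: str | None) -> str:
    """Leading/lagging call from the replication-direction region label.

    In a ``rep+`` (rightward-replicating) region a + strand pyrimidine is
    replicated as part of the leading strand template; the assignment
    mirrors in ``rep-`` regions and is ``unknown`` in ``*`` regions.
    """
    if region == "rep+":
        return "leading" if pyr_on_plus else "lagging"
    if region == "rep-":
        return "lagging" if pyr_on_plus else "leading"
    return "unknown"


@dataclass
class AnnotationSources:
    """Bundle of the annotation tracks used to place variants in states."""

    genes: GeneTrack | None = None
    replication: StateTrack | None = None
    epigenome: StateTrack | None = None
    dyads: DyadTrack | None = None


def annotate_variant(
    variant: VariantRecord,
    flank5: str,
    flank3: str,
    sources: AnnotationSources,
    clu_state: str = "unclustered",
) -> AnnotatedVariant:
    """Resolve all tensor coordinates for one variant.

    Non-SNVs get an ``other_category`` and neutral states.  Variants on
    contigs absent from a track fall back to that axis's baseline state.
    """
    if not variant.is_snv:
        return AnnotatedVariant(
            variant, snv_channel=None, other_category=classify_other(variant)
        )
    channel, pyr_on_plus = classify_snv(variant, flank5, flank3)
    pos0 = variant.pos - 1  # VCF 1-based -> BED 0-based, once, here
    tx = "unknown"
    if sources.genes is not None:
        tx = assign_transcription_state(
            pyr_on_plus, sources.genes.strands_at(variant.chrom, pos0)
        )
    rep = "unknown"
    if sources.replication is not None:
        rep = assign_replication_state(
            pyr_on_plus, sources.replication.lookup(variant.chrom, pos0)
        )
    epi = "variable"
    if sources.epigenome is not None:
        epi = sources.epigenome.lookup(variant.chrom, pos0, default="variable")
    nuc = "none"
    if sources.dyads is not None:
        nuc = sources.dyads.nucleosome_state(variant.chrom, pos0)
    return AnnotatedVariant(variant, channel, tx, rep, epi, nuc, clu_state)


# ---------------------------------------------------------------------------
# tensor assembly


def build_count_tensor(
    annotated: list[AnnotatedVariant],
    sample_ids: list[str],
    axis_labels: dict[str, tuple[str, ...]] | None = None,
    category_labels: list[str] | None = None,
) -> tuple[CountTensor, OtherCountMatrix]:
    """Tally annotated variants into the SNV tensor and the other matrix.

    ``sample_ids`` fixes the sample axis; a variant with an unlisted
    sample id is an error.  ``category_labels`` may pre-specify the other
    axis (useful for aligning cohorts); otherwise the categories observed
    in the input are used, sorted.
    """
    labels = dict(DEFAULT_AXIS_LABELS if axis_labels is None else axis_labels)
    index = {
        axis: {lab: i for i, lab in enumerate(labels[axis])}
        for axis in AXIS_NAMES[:-1]
    }
    sample_index = {sid: j for j, sid in enumerate(sample_ids)}
    shape = tuple(len(labels[a]) for a in AXIS_NAMES[:-1]) + (len(sample_ids),)
    snv = np.zeros(shape, dtype=np.int64)

    others: list[tuple[str, str]] = []
    for av in annotated:
        sid = av.variant.sample_id
        if sid not in sample_index:
            raise KeyError(f"unknown sample id {sid!r}")
        if av.snv_channel is None:
            others.append((av.other_category or "other", sid))
            continue
        snv[
            index["transcription"][av.tx_state],
            index["replication"][av.rep_state],
            index["epigenome"][av.epi_state],
            index["nucleosome"][av.nuc_state],
            index["cluster"][av.clu_state],
            av.snv_channel,
            sample_index[sid],
        ] += 1

    if category_labels is None:
        category_labels = sorted({cat for cat, _ in others})
    cat_index = {c: i for i, c in enumerate(category_labels)}
    other = np.zeros((len(category_labels), len(sample_ids)), dtype=np.int64)
    for cat, sid in others:
        if cat not in cat_index:
            raise KeyError(f"category {cat!r} not in category_labels")
        other[cat_index[cat], sample_index[sid]] += 1

    return (
        CountTensor(snv, labels, list(sample_ids)),
        OtherCountMatrix(other, list(category_labels), list(sample_ids)),
    )
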