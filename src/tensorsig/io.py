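"""File readers and the end-to-end catalogue pipeline.

Variants come from VCF (single- or multi-sample; sample membership from
non-reference genotypes, or a forced sample id); SVs from BEDPE; genes
from BED6 or GTF; replication timing from bedGraph; ChromHMM and dyads
from BED4.  Coordinates are converted exactly once: VCF positions are
1-based, interval tracks are 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

from .catalogue import (
    AnnotatedVariant,
    AnnotationSources,
    CountTensor,
    OtherCountMatrix,
    annotate_variant,
    build_count_tensor,
)
from .channels import VariantRecord, VariantRejected
from .kataegis import HmmParameters, call_clusters_per_sample
from .tracks import (
    CHROMHMM_STATES,
    DyadTrack,
    EPI_LABELS,
    GeneTrack,
    StateTrack,
    build_epigenome_consensus,
    build_replication_track,
)

log = logging.getLogger(__name__)


def read_vcf(path: str | Path, sample: str | None = None) -> tuple[list[VariantRecord], list[str]]:
    """Read SNV/MNV/indel records from a VCF.

    Multi-allelic records are split.  In a multi-sample VCF a variant is
    attributed to every sample with a non-reference genotype; ``sample``
    forces a single sample id instead (required for site-only VCFs).
    """
    vcf = VCF(str(path))
    sample_ids = [sample] if sample is not None else list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"{path} has no genotype columns; pass an explicit sample id")
    records: list[VariantRecord] = []
    for rec in vcf:
        if sample is not None:
            carriers = [sample]
        else:
            gts = rec.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            carriers = [
                sid for sid, g in zip(vcf.samples, gts) if g in (1, 3)
            ]
        for alt in rec.ALT:
            for sid in carriers:
                records.append(
                    VariantRecord(rec.CHROM, rec.POS, rec.REF, alt, sid)
                )
    return records, sample_ids


def read_bedpe(path: str | Path, sample: str) -> list[VariantRecord]:
    """Structural variants from a BEDPE with a type column (7th or 'svtype')."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    records = []
    for _, row in df.iterrows():
        chrom1, start1 = row[0], int(row[1])
        chrom2, start2 = row[3], int(row[4])
        svtype = str(row[6]) if len(row) > 6 else "SV"
        length = abs(start2 - start1) if chrom1 == chrom2 else None
        records.append(
            VariantRecord(str(chrom1), start1 + 1, "N", "<SV>", sample,
                          sv_type=svtype, sv_length=length)
        )
    return records


def read_gene_bed(path: str | Path) -> GeneTrack:
    """Stranded gene intervals from BED6."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return GeneTrack(df[["chrom", "start", "end", "strand"]])


def read_gene_gtf(path: str | Path) -> GeneTrack:
    """Gene intervals from a GTF (feature type 'gene'; GTF is 1-based closed)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "feature", "start", "end", "score",
               "strand", "frame", "attribute"],
    )
    genes = df[df["feature"] == "gene"].copy()
    genes["start"] = genes["start"] - 1
    return GeneTrack(genes[["chrom", "start", "end", "strand"]])


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"], usecols=range(4),
    )


def read_state_bed(path: str | Path, axis_name: str = "epigenome",
                   label_set: tuple[str, ...] | None = None) -> StateTrack:
    """A BED4 of labelled intervals (e.g. one cell line's ChromHMM calls)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "label"], usecols=range(4),
    )
    if label_set is None:
        label_set = tuple(dict.fromkeys(list(CHROMHMM_STATES) + sorted(set(df["label"]))))
    return StateTrack(df, axis_name=axis_name, label_set=label_set)


def read_dyads(path: str | Path) -> DyadTrack:
    """Nucleosome dyad midpoints from a BED (start column, 0-based)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "pos"], usecols=range(2),
    )
    return DyadTrack(df)


# ---------------------------------------------------------------------------
# pipeline


def prepare(
    vcf: str | Path,
    fasta: str | Path,
    genes: str | Path | None = None,
    repliseq: list[str | Path] | None = None,
    chromhmm: list[str | Path] | None = None,
    dyads: str | Path | None = None,
    bedpe: str | Path | None = None,
    sample: str | None = None,
    agreement: float = 0.70,
    hmm_params: HmmParameters | None = None,
) -> tuple[CountTensor, OtherCountMatrix, pd.DataFrame]:
    """Annotate a VCF against the tracks and build the count tensor.

    Returns the SNV tensor, the other-mutation matrix, and the
    per-variant annotation table.  Rejected variants (non-ACGT alleles)
    are logged and skipped.
    """
    records, sample_ids = read_vcf(vcf, sample=sample)
    if bedpe is not None:
        if sample is None and len(sample_ids) > 1:
            raise ValueError("BEDPE input requires a single sample id")
        records += read_bedpe(bedpe, sample or sample_ids[0])
    ref = Fasta(str(fasta))
    sources = AnnotationSources(
        genes=read_gene_bed(genes) if genes is not None else None,
        replication=(
            build_replication_track([read_bedgraph(p) for p in repliseq])
            if repliseq else None
        ),
        epigenome=(
            build_epigenome_consensus(
                [read_state_bed(p, label_set=EPI_LABELS) for p in chromhmm],
                agreement=agreement,
            )
            if chromhmm else None
        ),
        dyads=read_dyads(dyads) if dyads is not None else None,
    )

    # kataegis labels from SNV positions, per sample
    snv_records = [r for r in records if r.is_snv]
    clu_lookup: dict[tuple[str, str, int], str] = {}
    if snv_records:
        table = pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in snv_records],
                "chrom": [r.chrom for r in snv_records],
                "pos": [r.pos for r in snv_records],
            }
        ).sort_values(["sample_id", "chrom", "pos"])
        for call in call_clusters_per_sample(table, params=hmm_params):
            for pos, lab in zip(call.positions, call.labels):
                clu_lookup[(call.sample_id, call.chrom, int(pos))] = (
                    "clustered" if lab else "unclustered"
                )

    annotated: list[AnnotatedVariant] = []
    rows = []
    for rec in records:
        try:
            if rec.is_snv:
                chrom_seq = ref[rec.chrom]
                f5 = str(chrom_seq[rec.pos - 2]) if rec.pos >= 2 else "N"
                f3 = str(chrom_seq[rec.pos]) if rec.pos < len(chrom_seq) else "N"
                clu = clu_lookup.get((rec.sample_id, rec.chrom, rec.pos), "unclustered")
                av = annotate_variant(rec, f5, f3, sources, clu_state=clu)
            else:
                av = annotate_variant(rec, "N", "N", sources)
        except VariantRejected:
            continue
        annotated.append(av)
        rows.append(
            {
                "sample_id": rec.sample_id, "chrom": rec.chrom, "pos": rec.pos,
                "ref": rec.ref, "alt": rec.alt, "channel": av.snv_channel,
                "tx": av.tx_state, "rep": av.rep_state, "epi": av.epi_state,
                "nuc": av.nuc_state, "clu": av.clu_state,
                "category": av.other_category,
            }
        )
    tensor, other = build_count_tensor(annotated, sample_ids)
    return tensor, other, pd.DataFrame(rows)
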