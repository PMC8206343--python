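"""Mutation-type channel definitions and per-variant classification.

Single base substitutions are expressed in the pyrimidine convention: the
mutated Watson-Crick pair is reported with its C or T on the reference
(+) strand, reverse-complementing purine-reference calls.  Together with
the two flanking reference bases this yields the standard 96 trinucleotide
channels (6 substitution types x 4 x 4 flanks).

MNVs, indels and SVs are mapped to a flat category catalogue
(:func:`classify_other`); the default scheme is deliberately coarse and
configurable, since no community-standard taxonomy fixes these classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

log = logging.getLogger(__name__)

BASES = "ACGT"
PYRIMIDINES = "CT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six pyrimidine-reference substitution types, COSMIC order
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: all 96 channel labels, e.g. ``"A[C>T]G"``; index = 16*sub + 4*five + three
CHANNEL_LABELS = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTION_TYPES for f5 in BASES for f3 in BASES
)

_CHANNEL_INDEX = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class VariantRecord:
    """A single somatic variant call (1-based VCF-style coordinates)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    sv_type: str | None = None  # set for SV records (DEL/DUP/INV/TRA ...)
    sv_length: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt) and self.sv_type is None

    @property
    def is_mnv(self) -> bool:
        return (
            self.sv_type is None
            and len(self.ref) == len(self.alt)
            and len(self.ref) >= 2
        )

    @property
    def is_indel(self) -> bool:
        return self.sv_type is None and len(self.ref) != len(self.alt)

    @property
    def is_sv(self) -> bool:
        return self.sv_type is not None


class VariantRejected(ValueError):
    """Raised when a variant cannot be classified (e.g. non-ACGT alleles)."""


def classify_snv(variant: VariantRecord, flank5: str, flank3: str) -> tuple[int, bool]:
    """Classify an SNV into one of the 96 pyrimidine-context channels.

    Parameters
    ----------
    variant
        An SNV record; ``ref`` and ``alt`` must be single bases.
    flank5, flank3
        Reference bases immediately 5' and 3' of the variant on the + strand.

    Returns
    -------
    (channel, ref_pyrimidine_on_plus)
        ``channel`` indexes :data:`CHANNEL_LABELS`;  the flag records whether
        the pyrimidine of the mutated base pair lies on the + reference
        strand (False means the call was reverse-complemented).
    """
    if not variant.is_snv:
        raise VariantRejected(f"not an SNV: {variant.ref}>{variant.alt}")
    ref, alt = variant.ref.upper(), variant.alt.upper()
    f5, f3 = flank5.upper(), flank3.upper()
    for b in (ref, alt, f5, f3):
        if len(b) != 1 or b not in BASES:
            log.warning(
                "rejecting variant %s:%d %s>%s (non-ACGT allele or flank %r)",
                variant.chrom, variant.pos, variant.ref, variant.alt, b,
            )
            raise VariantRejected(f"non-ACGT base {b!r}")
    if ref in PYRIMIDINES:
        pyr_on_plus = True
    else:
        pyr_on_plus = False
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        f5, f3 = COMPLEMENT[f3], COMPLEMENT[f5]
    channel = _CHANNEL_INDEX[f"{f5}[{ref}>{alt}]{f3}"]
    return channel, pyr_on_plus


# ---------------------------------------------------------------------------
# other mutation types: MNV / indel / SV category catalogue


def _pyrimidine_dinucleotide(ref: str, alt: str) -> tuple[str, str]:
    """Canonical orientation of a dinucleotide substitution.

    The strand is chosen so that the (ref, alt) pair is lexicographically
    minimal, which makes the label strand-symmetric.
    """
    rc = (reverse_complement(ref), reverse_complement(alt))
    return min((ref, alt), rc)


_SV_LENGTH_BINS = ((1_000, "lt1kb"), (10_000, "1-10kb"), (100_000, "10-100kb"),
                   (1_000_000, "100kb-1Mb"))


def classify_other(variant: VariantRecord, homopolymer_run: int | None = None) -> str:
    """Map a non-SNV variant to a category label.

    The default catalogue (documented in the README) is:

    * MNVs: dinucleotides as strand-symmetric ``mnv.XY>ZW`` labels
      (78 classes), longer MNVs as ``mnv.len3`` / ``mnv.len4plus``;
    * indels: 1 bp insertions/deletions by pyrimidine-strand base and,
      when a reference context is supplied, the length of the
      mononucleotide run they fall in (capped at 5), longer events by
      length bucket;
    * SVs: type x length bucket (translocations have no length).

    Unclassifiable records fall into an ``"other"`` bucket and are logged.
    """
    if variant.is_sv:
        svt = (variant.sv_type or "SV").upper()
        if svt == "TRA" or variant.sv_length is None:
            return f"sv.{svt}"
        for bound, name in _SV_LENGTH_BINS:
            if abs(variant.sv_length) < bound:
                return f"sv.{svt}.{name}"
        return f"sv.{svt}.ge1Mb"
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if variant.is_mnv:
        if len(ref) == 2:
            r, a = _pyrimidine_dinucleotide(ref, alt)
            return f"mnv.{r}>{a}"
        return "mnv.len3" if len(ref) == 3 else "mnv.len4plus"
    if variant.is_indel:
        if len(ref) > len(alt):
            kind, delta = "del", len(ref) - len(alt)
            changed = ref[len(alt):]
        else:
            kind, delta = "ins", len(alt) - len(ref)
            changed = alt[len(ref):]
        if delta == 1 and changed in BASES:
            base = changed if changed in PYRIMIDINES else COMPLEMENT[changed]
            if homopolymer_run is not None:
                run = min(int(homopolymer_run), 5)
                return f"{kind}.1bp.{base}.rep{run}"
            return f"{kind}.1bp.{base}"
        if delta <= 5:
            return f"{kind}.{delta}bp"
        return f"{kind}.gt5bp"
    log.warning("unclassifiable non-SNV record %s:%d %s>%s",
                variant.chrom, variant.pos, variant.ref, variant.alt)
    return "other"
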