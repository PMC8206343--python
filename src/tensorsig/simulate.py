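"""Synthetic data generation at two levels.

Parameter level: draw a ground-truth signature model (spectra, strand
biases, amplitudes, state activities, exposures) and sample
negative-binomial count tensors from it — this is what the factorisation
and model-selection experiments consume.

Variant level: build a toy genome with gene, replication-timing,
ChromHMM and nucleosome-dyad tracks plus a multi-sample VCF whose
variants have known channels, states and planted kataegis clusters —
this exercises the annotation and clustering code through the same file
readers used for real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalogue import DEFAULT_AXIS_LABELS, AXIS_NAMES, CountTensor, OtherCountMatrix
from .channels import BASES, CHANNEL_LABELS, PYRIMIDINES, reverse_complement
from .model import (
    CoreSpectra,
    ExposureMatrix,
    TensorFactors,
    assemble_signature_tensor,
    expected_counts,
)
from .tracks import CHROMHMM_STATES


def synthetic_axis_labels(
    state_sizes: tuple[int, int, int] = (16, 4, 2), p: int = 96
) -> dict[str, tuple[str, ...]]:
    """Axis labels for a (possibly scaled-down) tensor shape."""
    labels = dict(DEFAULT_AXIS_LABELS)
    te, tn, tc = state_sizes
    if te != 16:
        labels["epigenome"] = ("variable",) + tuple(f"state{i}" for i in range(1, te))
    if tn != 4:
        labels["nucleosome"] = ("none",) + tuple(f"nuc{i}" for i in range(1, tn))
    if tc != 2:
        labels["cluster"] = ("unclustered",) + tuple(f"clu{i}" for i in range(1, tc))
    if p != 96:
        labels["channel"] = tuple(f"ch{i}" for i in range(p))
    return labels


@dataclass(frozen=True)
class TruthPriors:
    """Distributions the ground-truth parameters are drawn from.

    Spectra are symmetric Dirichlet (alpha = 0.5 gives realistically
    spiky signatures); biases, amplitudes and state activities are
    log-normal with sd 0.25 around neutral; the SNV fraction is
    Beta(9, 1) (mutation catalogues are SNV-dominated); exposures are
    log-normal and rescaled so the median sample carries
    ``mutations_per_sample`` expected mutations.
    """

    dirichlet_alpha: float = 0.5
    log_sd: float = 0.25
    m_beta: tuple[float, float] = (9.0, 1.0)
    exposure_log_sd: float = 0.5
    mutations_per_sample: float = 1000.0
    n_categories: int = 12


@dataclass
class SimulationTruth:
    """Ground-truth parameters plus the implied expected counts."""

    core: CoreSpectra
    factors: TensorFactors
    exposures: ExposureMatrix
    tau: float
    mu_snv: np.ndarray
    mu_other: np.ndarray
    axis_labels: dict[str, tuple[str, ...]] = field(default_factory=dict)
    seed: int | None = None

    @property
    def rank(self) -> int:
        return self.factors.rank


def sample_truth(
    s: int,
    n: int,
    seed: int = 0,
    priors: TruthPriors = TruthPriors(),
    state_sizes: tuple[int, int, int] = (16, 4, 2),
    p: int = 96,
    tau: float = 50.0,
    overrides: dict[str, np.ndarray] | None = None,
) -> SimulationTruth:
    """Draw a ground-truth model of rank ``s`` over ``n`` samples.

    ``overrides`` replaces named factor fields (e.g. fixed strand biases
    for a recovery experiment) after sampling; exposures are rescaled to
    the target mutation load afterwards either way.
    """
    if s < 1 or n < 1:
        raise ValueError("s and n must be >= 1")
    rng = np.random.default_rng(seed)
    te, tn, tc = state_sizes
    a = priors.dirichlet_alpha
    t0 = rng.dirichlet(np.full(p, a), size=(2, 2, s)).transpose(0, 1, 3, 2)
    core = CoreSpectra(t0)

    def logn(size):
        return np.exp(rng.normal(0.0, priors.log_sd, size))

    q = priors.n_categories
    factors = TensorFactors(
        b_t=logn(s), b_r=logn(s), a_t=logn(s), a_r=logn(s),
        m=rng.beta(*priors.m_beta, size=s),
        k_epi=np.vstack([np.ones((1, s)), logn((te - 1, s))]),
        k_nuc=np.vstack([np.ones((1, s)), logn((tn - 1, s))]),
        k_clu=np.vstack([np.ones((1, s)), logn((tc - 1, s))]),
        s0=rng.dirichlet(np.full(q, a), size=s).T,
    )
    if overrides:
        fields = {k: np.asarray(v, dtype=float) for k, v in overrides.items()}
        factors = TensorFactors(**{
            name: fields.get(name, getattr(factors, name))
            for name in ("b_t", "b_r", "a_t", "a_r", "m",
                         "k_epi", "k_nuc", "k_clu", "s0")
        })

    e = np.exp(rng.normal(0.0, priors.exposure_log_sd, (s, n)))
    t = assemble_signature_tensor(core, factors)
    mass = t.t.reshape(-1, s).sum(axis=0) + (factors.s0 * (1 - factors.m)).sum(axis=0)
    target = priors.mutations_per_sample * np.exp(
        rng.normal(0.0, 0.3, n)
    )
    e *= target / (mass @ e)
    exposures = ExposureMatrix(e)
    mu_snv, mu_other = expected_counts(t, factors.s0, factors.m, exposures)
    return SimulationTruth(
        core, factors, exposures, tau, mu_snv, mu_other,
        axis_labels=synthetic_axis_labels(state_sizes, p), seed=seed,
    )


def sample_counts(
    truth: SimulationTruth, tau: float | None = None, seed: int = 0
) -> tuple[CountTensor, OtherCountMatrix]:
    """Draw one negative-binomial count realisation from the truth.

    Cells are independent NB with mean mu and dispersion tau, i.e.
    variance mu + mu^2 / tau; a zero mean always yields a zero count.
    """
    rng = np.random.default_rng(seed)
    tau = truth.tau if tau is None else tau
    p_snv = tau / (tau + truth.mu_snv)
    snv = rng.negative_binomial(tau, p_snv).astype(np.int64)
    p_oth = tau / (tau + truth.mu_other)
    oth = rng.negative_binomial(tau, p_oth).astype(np.int64)
    n = truth.exposures.e.shape[1]
    sample_ids = [f"S{i:03d}" for i in range(n)]
    tensor = CountTensor(snv, truth.axis_labels, sample_ids)
    q = truth.mu_other.shape[0]
    other = OtherCountMatrix(oth, [f"cat{i:02d}" for i in range(q)], sample_ids)
    return tensor, other


# ---------------------------------------------------------------------------
# variant-level fixture


@dataclass
class VariantFixture:
    """Paths and planted truth of a toy variant-level dataset."""

    fasta: Path
    genes_bed: Path
    repliseq_bedgraphs: list[Path]
    chromhmm_beds: list[Path]
    dyads_bed: Path
    vcf: Path
    truth: pd.DataFrame  # one row per variant with all intended states
    cluster_segments: pd.DataFrame  # planted kataegis runs
    sample_ids: list[str]


# toy-genome layout constants
_CHROM_LEN = 600_000
_GENE_LEN = 20_000
_GENE_SPACING = 50_000
_REP_PERIOD = 200_000  # triangle wave period: 100 kb up, 100 kb down
_REP_BIN = 10_000
_HMM_BLOCK = 50_000
_DYAD_REGION = (400_000, 500_000)
_DYAD_SPACING = 400


def _write_fasta(path: Path, genome: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def make_variant_fixture(
    seed: int,
    outdir: Path | str,
    n_samples: int = 3,
    n_unclustered: int = 400,
    n_clusters: int = 4,
    cluster_size: tuple[int, int] = (8, 15),
) -> VariantFixture:
    """Write a toy genome, annotation tracks and a multi-sample VCF.

    The genome layout is deterministic given the seed: genes alternate
    strand on a regular grid, replication timing is a triangle wave
    (slopes are exactly known per bin), ChromHMM blocks mostly agree
    across five simulated cell lines, and nucleosome dyads sit on a
    400 bp grid inside one region.  Variants are placed at positions
    whose states are unambiguous by construction and the intended state
    of every variant is recorded — the annotation code can be checked
    against this table exactly.  Kataegis clusters use geometric
    intra-cluster spacing with mean 100 bp.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms = ["chr1", "chr2"]
    genome = {
        c: "".join(rng.choice(list(BASES), size=_CHROM_LEN)) for c in chroms
    }
    _write_fasta(outdir / "genome.fa", genome)

    # genes: alternating strand, one per 50 kb, occupying [s, s + 20 kb)
    gene_rows = []
    for chrom in chroms:
        for gi, start in enumerate(range(10_000, _CHROM_LEN - _GENE_LEN, _GENE_SPACING)):
            strand = "+" if gi % 2 == 0 else "-"
            gene_rows.append((chrom, start, start + _GENE_LEN,
                              f"gene_{chrom}_{gi}", 0, strand))
    genes = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    genes_bed = outdir / "genes.bed"
    genes.to_csv(genes_bed, sep="\t", header=False, index=False)

    # replication timing: triangle wave shared by five noisy-free profiles
    rep_paths = []
    for k in range(5):
        rows = []
        for chrom in chroms:
            for start in range(0, _CHROM_LEN, _REP_BIN):
                phase = (start % _REP_PERIOD) / _REP_PERIOD
                value = 2 * phase if phase < 0.5 else 2 * (1 - phase)
                rows.append((chrom, start, start + _REP_BIN, round(100 * value, 3)))
        path = outdir / f"repliseq_{k}.bedgraph"
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
        rep_paths.append(path)

    # ChromHMM: 50 kb blocks; block state cycles through the vocabulary;
    # every 5th block disagrees across cell lines (consensus 'variable')
    hmm_paths = []
    block_truth: dict[tuple[str, int], str] = {}
    for chrom in chroms:
        for bi, start in enumerate(range(0, _CHROM_LEN, _HMM_BLOCK)):
            state = CHROMHMM_STATES[bi % len(CHROMHMM_STATES)]
            block_truth[(chrom, bi)] = "variable" if bi % 5 == 4 else state
    for k in range(5):
        rows = []
        for chrom in chroms:
            for bi, start in enumerate(range(0, _CHROM_LEN, _HMM_BLOCK)):
                state = CHROMHMM_STATES[bi % len(CHROMHMM_STATES)]
                if bi % 5 == 4:  # disagreement block: each line says its own
                    state = CHROMHMM_STATES[(bi + k) % len(CHROMHMM_STATES)]
                rows.append((chrom, start, min(start + _HMM_BLOCK, _CHROM_LEN), state))
        path = outdir / f"chromhmm_{k}.bed"
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
        hmm_paths.append(path)

    # dyads on a regular grid inside one region of chr1
    dyad_positions = list(range(_DYAD_REGION[0], _DYAD_REGION[1], _DYAD_SPACING))
    dyads_bed = outdir / "dyads.bed"
    pd.DataFrame(
        [("chr1", p, p + 1, "dyad") for p in dyad_positions]
    ).to_csv(dyads_bed, sep="\t", header=False, index=False)

    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    variants, cluster_rows = _place_variants(
        rng, genome, genes, block_truth, dyad_positions, sample_ids,
        n_unclustered, n_clusters, cluster_size,
    )
    truth = pd.DataFrame(variants)
    vcf_path = outdir / "variants.vcf"
    _write_vcf(vcf_path, truth, sample_ids, chrom_lengths={c: _CHROM_LEN for c in chroms})
    return VariantFixture(
        fasta=outdir / "genome.fa",
        genes_bed=genes_bed,
        repliseq_bedgraphs=rep_paths,
        chromhmm_beds=hmm_paths,
        dyads_bed=dyads_bed,
        vcf=vcf_path,
        truth=truth.sort_values(["chrom", "pos"]).reset_index(drop=True),
        cluster_segments=pd.DataFrame(
            cluster_rows, columns=["sample_id", "chrom", "start", "end", "n_variants"]
        ),
        sample_ids=sample_ids,
    )


def _triangle_value(bin_index: int) -> float:
    phase = (bin_index * _REP_BIN % _REP_PERIOD) / _REP_PERIOD
    # rounded so the rising and falling arms are exactly symmetric, as in
    # the written bedGraph
    return round(2 * phase if phase < 0.5 else 2 * (1 - phase), 9)


def _rep_state_at(pos: int, chrom_len: int = _CHROM_LEN) -> str:
    """rep+ on rising half-wave, rep- on falling, '*' at turning-point bins.

    The truth mirrors the finite-difference slope of the known triangle
    wave at bin resolution (central differences, one-sided at chromosome
    ends), so peak and valley bins — where the centred slope is exactly
    zero — carry the unknown state.
    """
    i = pos // _REP_BIN
    last = chrom_len // _REP_BIN - 1
    lo, hi = max(i - 1, 0), min(i + 1, last)
    slope = _triangle_value(hi) - _triangle_value(lo)
    if slope > 0:
        return "rep+"
    if slope < 0:
        return "rep-"
    return "*"


def _nuc_state_at(chrom: str, pos0: int, dyads: list[int]) -> str:
    if chrom != "chr1":
        return "none"
    lo, hi = _DYAD_REGION
    if not lo - 200 <= pos0 <= hi + 200:
        return "none"
    nearest = min(dyads, key=lambda d: abs(pos0 - d))
    offset = abs(pos0 - nearest)
    if offset <= 7:
        return "minor_in"
    k = (offset - 8) // 5
    if k < 10:
        return "minor_out" if k % 2 == 0 else "minor_in"
    return "linker" if offset <= 115 else "none"


def _place_variants(rng, genome, genes, block_truth, dyads, sample_ids,
                    n_unclustered, n_clusters, cluster_size):
    gene_lookup = {
        chrom: grp[["start", "end", "strand"]].to_numpy(object)
        for chrom, grp in genes.groupby("chrom", sort=False)
    }

    def gene_strands(chrom, pos0):
        out = set()
        for s, e, st in gene_lookup.get(chrom, []):
            if s <= pos0 < e:
                out.add(st)
        return out

    def snv_at(chrom, pos0, sample_id, clustered):
        seq = genome[chrom]
        if not 1 <= pos0 < len(seq) - 1:
            return None
        ref = seq[pos0]
        alt = rng.choice([b for b in BASES if b != ref])
        pyr_on_plus = ref in PYRIMIDINES
        strands = gene_strands(chrom, pos0)
        if len(strands) == 1:
            gstrand = next(iter(strands))
            tx = "coding" if (("+" if pyr_on_plus else "-") == gstrand) else "template"
        else:
            tx = "unknown"
        region = _rep_state_at(pos0)
        if region == "rep+":
            rep = "leading" if pyr_on_plus else "lagging"
        elif region == "rep-":
            rep = "lagging" if pyr_on_plus else "leading"
        else:
            rep = "unknown"
        epi = block_truth[(chrom, pos0 // _HMM_BLOCK)]
        nuc = _nuc_state_at(chrom, pos0, dyads)
        if pyr_on_plus:
            f5, f3, r, a = seq[pos0 - 1], seq[pos0 + 1], ref, alt
        else:
            f5, f3 = reverse_complement(seq[pos0 + 1]), reverse_complement(seq[pos0 - 1])
            r, a = reverse_complement(ref), reverse_complement(alt)
        channel = CHANNEL_LABELS.index(f"{f5}[{r}>{a}]{f3}")
        return {
            "chrom": chrom, "pos": pos0 + 1, "ref": ref, "alt": alt,
            "sample_id": sample_id, "channel": channel, "tx": tx, "rep": rep,
            "epi": epi, "nuc": nuc, "clu": "clustered" if clustered else "unclustered",
        }

    variants = []
    cluster_rows = []
    occupied: set[tuple[str, int]] = set()
    for sid in sample_ids:
        # unclustered background: positions far apart (>= 2 kb spacing)
        for chrom in genome:
            n_bg = n_unclustered // (2 * len(sample_ids)) * 2  # even split
            positions = np.sort(
                rng.choice(np.arange(1000, _CHROM_LEN - 1000, 2000), size=n_bg // 2,
                           replace=False)
            ) + rng.integers(0, 500, size=n_bg // 2)
            for pos0 in positions:
                key = (chrom, int(pos0))
                if key in occupied:
                    continue
                v = snv_at(chrom, int(pos0), sid, clustered=False)
                if v is not None:
                    variants.append(v)
                    occupied.add(key)
        # planted kataegis clusters with geometric spacing, mean 100 bp
        for _ in range(n_clusters):
            chrom = rng.choice(list(genome))
            start0 = int(rng.integers(5_000, _CHROM_LEN - 10_000))
            size = int(rng.integers(cluster_size[0], cluster_size[1] + 1))
            pos0 = start0
            placed = []
            for _ in range(size):
                key = (chrom, pos0)
                if key not in occupied:
                    v = snv_at(chrom, pos0, sid, clustered=True)
                    if v is not None:
                        variants.append(v)
                        placed.append(pos0)
                        occupied.add(key)
                pos0 += int(rng.geometric(1.0 / 100.0))
            if len(placed) >= 2:
                cluster_rows.append(
                    (sid, chrom, placed[0] + 1, placed[-1] + 1, len(placed))
                )
    return variants, cluster_rows


def _write_vcf(path: Path, truth: pd.DataFrame, sample_ids: list[str],
               chrom_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        ordered = truth.sort_values(["chrom", "pos"])
        for _, row in ordered.iterrows():
            gts = ["0/1" if sid == row.sample_id else "0/0" for sid in sample_ids]
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
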