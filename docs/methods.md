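# Methods

## Count tensor

Single base substitutions are expressed in the pyrimidine convention
(the mutated pair reported with its C or T as reference; purine-
reference calls are reverse-complemented, swapping and complementing the
flanks) and classified into 96 trinucleotide channels. Every SNV is then
placed in five genomic states:

* **Transcription** — the genome is partitioned by gene direction
  (trx(+)/trx(−)). A gene transcribed from the − strand is read off the
  + strand, so its coding (untranscribed) strand is the − strand; the
  SNV is *coding* when the pyrimidine of the mutated pair lies on the
  gene's coding strand, *template* otherwise, and *unknown* outside
  genes or where overlapping genes disagree in direction. Coordinates
  are converted exactly once at ingest (VCF 1-based, tracks 0-based
  half-open).
* **Replication** — replication-timing profiles are differentiated per
  bin (central finite differences; one-sided at chromosome ends). A bin
  is rightward-replicating (rep+) when the mean slope across profiles is
  positive and exceeds twice their standard deviation, leftward (rep−)
  under the mirrored test, unknown (*) otherwise; a zero standard
  deviation with non-zero mean passes the test, so a single profile is
  usable. A + strand pyrimidine in a rep+ region is replicated as
  leading-strand template; the call mirrors in rep− regions.
* **Epigenome** — per-cell-line ChromHMM tracks are reduced to a
  consensus: a window keeps the modal state when its frequency reaches
  the agreement threshold (default 0.70), otherwise it becomes the 16th
  state *variable*, which is also the axis baseline.
* **Nucleosome** — around each dyad: positions within ±7 bp (core
  flank) are assigned *minor_in*; the next ten alternating 5 bp
  stretches are *minor_out* first, then alternating; then *linker* up to
  58 bp; beyond that *none*. Competing dyads are resolved by distance.
  The out-first phase after the flank and the assignment of the flank
  itself are conventions (the alternation's anchor is not fixed by the
  underlying biochemistry at ±1 stretch); both are isolated in
  `nucleosome_label` and tested explicitly.
* **Clustering** — see the kataegis section.

MNVs, indels and SVs go into a category × sample matrix. The default
catalogue (strand-symmetric dinucleotide classes, 1 bp indels by
pyrimidine base and homopolymer run length, SV type × length buckets) is
deliberately coarse; there is no community-standard taxonomy at the
granularity of published per-cohort class counts, so the catalogue is
configurable and documented rather than canonical.

## Kataegis HMM

Inter-mutation distances Y_k between consecutive SNVs on a chromosome
drive a two-state chain: initial P(clustered) = 0.01, self-transition
0.99, clustered emissions Geom(p = 1/100) (mean 100 bp) and unclustered
emissions Geom(p = 1/mean distance), with the mean taken per sample
across chromosomes (the genome-wide rate is the scale-bearing unit).
Geometric support is {1, 2, …}; same-position records collapse to
distance 1, and p is clipped to (1e−12, 1−1e−12). States are decoded by
log-space Viterbi; a variant is clustered when either adjacent emission
is clustered, so a run of r clustered emissions yields r + 1 clustered
variants and clusters always contain at least two. Chromosomes with
fewer than two variants are unclustered.

## Signature tensor and likelihood

The four strand-specific spectra are stacked into the 3 × 3 block
matrix T₁ (unknown rows/columns hold pairwise means, the corner the
grand mean), multiplied by the bias layout B (b on the oriented strand,
1/b on the other, 1 when unoriented), the amplitude layout A (a on
oriented rows/columns, 1 in the fully unoriented corner), the SNV
fraction m, and one activity matrix per state axis with its baseline row
fixed at 1. Broadcasting follows trailing-axis alignment with singleton
expansion; mismatched non-singleton axes are an error.

Counts are negative binomial with mean T × E (and (S₀ ⊙ (1−m)) × E for
the other matrix) and dispersion τ. τ is a fixed hyperparameter, default
50: the likelihood is used for comparison across ranks at fixed τ, and
50 gives variance μ + μ²/50, mild overdispersion typical of mutation
counts; a grid (e.g. {10, 50, 100}) can be fitted side by side through
the config. Identifiability: spectra carry the normalisation (each
96-block and each S₀ column sums to 1), overall scale lives in E.

## Optimisation

All constraints are enforced by construction: per-block softmax for
spectra and S₀, exp for b, a, k and E, logistic for m; baseline rows
are constants. Gradients of the log-likelihood are derived analytically
(the gradient through μ = T × E runs in a fused numba kernel; factor
gradients follow from the product structure, ∂L/∂log f = Σ over the
cells f multiplies of (∂L/∂T)⊙T) and verified against central finite
differences at relative error < 1e−5. The optimiser is Adam with a
learning rate decaying exponentially from 0.1 to 1e−3 over the epoch
budget; initial parameters are truncated-normal noise on the free
scale, except exposures, which start at the scale reproducing each
sample's observed total under the initial tensor mass (without this the
first epochs are spent matching orders of magnitude). A non-finite loss
triggers a restart at half the learning rate (bounded retries). Fits are
deterministic given the seed; the best of n_init restarts is kept.

μ is floored at 1e−10 inside the likelihood; under the positive
parametrisation μ = 0 with a positive count cannot occur.

**Epoch budgets.** The library default is 5,000 epochs (50,000 for
cohort-scale runs, via config). The test-suite experiments use 400–1,200
epochs: convergence probes show the loss trace flat and strand-bias
estimates changing by < 1% beyond ~600 epochs at 10⁴ mutations/sample,
so these are converged fits at desk scale, chosen as the package's
own working sizes.

## Model selection

BIC(s) = ln(n)·k(s) − 2·log L̂ with n the grand total of counts in both
inputs. The parameter count follows the parametrisation:

    k(s) = s·[4(p−1) + 4 + 1 + Σ_j (t_j − 1) + (q−1)] + s·n_samples

(four normalised spectra, b_t, b_r, a_t, a_r, m, free activity rows,
normalised S₀, exposures); at p = 96, q = 10, n = 5 samples and default
state axes this is 418 per signature-rank unit. Rank recovery requires
the likelihood gain per added signature to beat ln(n)·k(1); at 10³
mutations/sample on a desk-scale cohort the penalty dominates and BIC
correctly prefers smaller models, so the selection experiments simulate
10⁴ mutations/sample (the upper end of the grid the method is designed
for).

## Bootstrap

Each replicate draws ⌈2n/3⌉ samples without replacement, perturbs a
random 10% of the free parameters multiplicatively by exp(N(0, 0.1²))
(the published recipe is ambiguous between "10% of the estimates" and
"by 10%"; the chosen reading is configurable), refits with 1/10 of the
main epoch budget from this warm start, matches refitted signatures to
the reference by optimal (Hungarian) cosine-distance assignment, and is
accepted when the total-variation distance between probability-
normalised signature tensors — aggregated by max over signatures, mean
available by flag — stays below 0.2. Intervals are 5–95% percentiles
over accepted replicates.

These intervals measure refit stability under subsampling around one
dataset's MLE. Two caveats follow, verified on simulations: (i) the
spread of a 2/3-subsample statistic around the full-data estimate is
roughly half the variance of the estimate around the truth, so the
percentile intervals are conservative in width by about √2 relative to
true sampling error; (ii) with several spectrally similar signatures the
MLE of a strand bias carries a small mixing bias that no
resampling-around-the-MLE scheme can see. Empirically the 90% intervals
cover a simulated truth for roughly 50–80% of strand-bias parameters
depending on signature separation — they are honest stability
diagnostics, not calibrated frequentist intervals.

## Simulator

Two levels. Parameter level: spectra from symmetric Dirichlet(0.5)
(spiky, signature-like), biases/amplitudes/activities log-normal(0,
0.25²) around neutral, m ~ Beta(9, 1) (SNV-dominated catalogues),
exposures log-normal rescaled so the median sample carries the target
mutation load; counts are independent NB draws per tensor cell. Variant
level: a two-chromosome toy genome (600 kb each) with genes on a regular
alternating-strand grid, a triangle-wave replication profile (known
slope per bin), five ChromHMM tracks agreeing except in designated
blocks, dyads on a 400 bp grid in one region, and a multi-sample VCF
whose variants sit at positions whose states are unambiguous by
construction; the intended channel and states of every variant are
recorded, so the annotation pipeline can be checked against the planted
truth exactly, through the same file readers used for real data.

What the fixture does not emulate: realistic trinucleotide composition,
gene-density/replication-timing correlations, overlapping genes (present
in real annotation, covered by unit tests instead), and callable-genome
gaps. Passing the planted-truth tests therefore demonstrates correctness
of the classification rules and bookkeeping, not robustness to noisy
real-world tracks.

## Problem sizes in the validation suite

Recovery: rank 3, 100 samples, 10⁴ mutations/sample, three fit seeds.
Rank selection: ten replicates at 40 samples, 10⁴ mutations/sample,
epigenome axis scaled 16→4 states, ranks 1–6. Bootstrap coverage: ten
repeats at 24 samples, 2,500 mutations/sample, rank 3, 30 replicates
each. These sizes are the package's desk-scale working points; the
scaled-down epigenome axis changes only the axis length, not any rule
being tested.

## Known limitations

* τ is fixed, not estimated; model comparison across different τ values
  must use the optional grid.
* The bootstrap undercovers as discussed above.
* The other-mutation catalogue is a documented default, not a community
  standard; cross-cohort comparisons should pin an explicit catalogue.
* Exposure intervals are reported per sample only where a sample enters
  enough accepted replicates.
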