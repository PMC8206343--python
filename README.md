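# tensorsig

Strand- and state-aware mutational signature extraction from somatic
variant catalogues by non-negative tensor factorisation under a
negative-binomial likelihood.

## The problem

Conventional mutational signature analysis factorises a catalogue of
cancer genomes, a count matrix **C** ∈ ℕ₀^{96×n} over trinucleotide
channels, as **C** ≈ **S** × **E** with non-negative spectra **S** and
exposures **E** (NMF). This discards where in the genome mutations fall.
Many mutational processes, however, act asymmetrically on the two DNA
strands (transcription-coupled repair, replication fork asymmetry) and
unevenly across chromatin: their imprint is only visible when counts are
split by genomic context.

`tensorsig` arranges SNVs into a count tensor

    C^SNV ∈ ℕ₀^{3 × 3 × 16 × 4 × 2 × 96 × n}

over transcriptional strand (coding / template / unknown), replicational
strand (leading / lagging / unknown), 16 consensus ChromHMM states,
4 nucleosomal states (none / minor-in / minor-out / linker), clustering
status (kataegis vs background), 96 channels and n samples — 1152
genomic state combinations per channel. MNVs, indels and SVs are kept in
a conventional category × sample matrix C^other.

## The model

Each *tensor signature* s is parametrised by

* four normalised 96-channel spectra T₀^{C/L}, T₀^{C/G}, T₀^{T/L},
  T₀^{T/G} (coding/template × leading/lagging), stacked into a 3×3 block
  matrix T₁ whose unknown rows/columns hold the corresponding means;
* strand biases b_t, b_r > 0 (entering as b on one strand, 1/b on the
  other) and regional amplitudes a_t, a_r > 0 (transcribed vs
  untranscribed, early vs late replicating);
* an SNV fraction m ∈ [0,1] splitting mass between C^SNV and C^other;
* per-state activity scalars k_epi ∈ ℝ₊^{16}, k_nuc ∈ ℝ₊^{4},
  k_clu ∈ ℝ₊^{2} with the baseline state fixed at 1;
* a normalised spectrum S₀ over the other-mutation categories.

The full signature tensor is the broadcast product
T = T₁ ⊙ B ⊙ A ⊙ M ⊙ K_epi ⊙ K_nuc ⊙ K_clu, and counts are modelled as

    C^SNV ~ NB(T × E, τ),   C^other ~ NB((S₀ ⊙ (1−m)) × E, τ),

with exposures E ∈ ℝ₊^{s×n} and fixed dispersion τ (τ→∞ recovers
Poisson). Maximum likelihood is found by Adam on an unconstrained
parametrisation with analytically derived gradients; the rank s is
selected by BIC(s) = ln(n)·k(s) − 2·log L̂ with n the total mutation
count; parameter uncertainty comes from a subsample-perturb-refit
bootstrap with cosine-distance signature matching and a total-variation
acceptance filter. Kataegis labels come from a two-state HMM on
inter-mutation distances (geometric emissions, Viterbi decoding).

## Worked example

```python
import numpy as np
from tensorsig import FitConfig, fit
from tensorsig.simulate import TruthPriors, sample_counts, sample_truth
from tensorsig.bootstrap import match_signatures, _flat_signatures
from tensorsig.model import assemble_signature_tensor

truth = sample_truth(3, 40, seed=21, state_sizes=(4, 4, 2),
                     priors=TruthPriors(mutations_per_sample=10_000.0))
snv, other = sample_counts(truth, seed=22)
result = fit(snv, other, FitConfig(rank=3, epochs=400, n_init=1, seed=7))
print(round(result.loglik, 1), round(result.bic, 1))
```

prints `-759860.6 1536876.0`: the maximised NB log-likelihood of the
403,526 simulated mutations and the corresponding BIC at rank 3 (k(3) =
1329 parameters, penalty ln(n_obs)·k). Matching the fitted signatures
back to the simulated truth (`match_signatures`) gives spectra cosine
similarities above 0.99 and strand biases within a few percent — see
`examples/` for complete narrated scripts:

* `examples/simulate_and_fit.py` — parameter recovery on synthetic counts
* `examples/rank_selection.py` — BIC scan around the generating rank
* `examples/bootstrap_intervals.py` — confidence intervals for factors
* `examples/variant_pipeline.py` — toy genome → VCF/tracks → count tensor
* `examples/kataegis_calling.py` — clustered-mutation HMM on distances

A thin CLI mirrors the library
(`tensorsig simulate/prepare/kataegis/train/scan/boot/report`).

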