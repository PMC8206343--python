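"""Parameter recovery: simulate a 3-signature cohort and refit it.

Draws a ground-truth model with fixed strand biases, samples
negative-binomial counts, fits the factorisation at the true rank, and
compares the matched signatures with the truth.
"""

import numpy as np

from tensorsig import FitConfig, fit
from tensorsig.bootstrap import _flat_signatures, match_signatures
from tensorsig.model import assemble_signature_tensor
from tensorsig.simulate import TruthPriors, sample_counts, sample_truth

truth = sample_truth(
    3, 40, seed=21, state_sizes=(4, 4, 2),
    priors=TruthPriors(mutations_per_sample=10_000.0),
    overrides={"b_t": [1.0, 2.0, 0.5], "b_r": [1.5, 1.0, 0.7]},
)
snv, other = sample_counts(truth, seed=22)
print(f"simulated {int(snv.counts.sum()):,} SNVs across {len(snv.sample_ids)} samples")

result = fit(snv, other, FitConfig(rank=3, epochs=400, n_init=1, seed=7))
print(f"log-likelihood {result.loglik:,.1f}   BIC {result.bic:,.1f} "
      f"(k = {result.n_parameters} parameters)")

ref = assemble_signature_tensor(truth.core, truth.factors).t.reshape(-1, 3).T
cand = _flat_signatures(result)
perm = match_signatures(cand, ref)
for i in range(3):
    cos = cand[perm[i]] @ ref[i] / (
        np.linalg.norm(cand[perm[i]]) * np.linalg.norm(ref[i])
    )
    print(f"signature {i + 1}: spectra cosine {cos:.4f}   "
          f"b_t {result.factors.b_t[perm[i]]:.3f} (truth {truth.factors.b_t[i]})   "
          f"b_r {result.factors.b_r[perm[i]]:.3f} (truth {truth.factors.b_r[i]})")

# cosine near 1 means the strand-resolved spectra are recovered; the
# fitted strand biases should sit within a few percent of the simulated
# values at this mutation load.
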