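"""Kataegis detection: the two-state HMM on inter-mutation distances.

Clustered mutations emit short geometric distances (mean 100 bp);
unclustered ones emit distances at the genome-wide mean rate.  The
Viterbi path labels every variant, and maximal clustered runs form
clusters.
"""

import numpy as np

from tensorsig.kataegis import call_clusters, summarise_clusters

rng = np.random.default_rng(1)
background = np.sort(rng.choice(np.arange(1, 10**7, 5000), 300, replace=False))
kataegis = 2_000_000 + np.cumsum(rng.geometric(1 / 100, size=12))
positions = np.sort(np.concatenate([background, kataegis]))

call = call_clusters(positions, chrom="chr1", sample_id="tumourA")
table = summarise_clusters([call])
print(f"{len(positions)} variants, {int(call.labels.sum())} labelled clustered")
print(table.to_string(index=False))

# each row is one maximal run of clustered variants: its genomic span in
# bp and how many variants it contains; the planted cluster of 12
# closely spaced variants near 2 Mb should be recovered as one run.
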