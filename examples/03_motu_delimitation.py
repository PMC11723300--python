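"""MOTU delimitation with ABGD and the ASAP-style ranker.

Both methods cluster specimens into molecular operational taxonomic units
from the pairwise distance matrix alone; their output is scored against
the known species labels with the strict one-to-one match rule.
"""

from barcodekit import (
    SimConfig,
    abgd_partition,
    asap_partition,
    choose_abgd_partition,
    distance_matrix,
    match_partition,
    simulate_sequences,
)

datasets, taxonomy = simulate_sequences(SimConfig(seed=0))
matrix = distance_matrix(datasets["ITS"], model="p")

partitions = abgd_partition(matrix)
print("ABGD MOTU counts per prior:",
      [(round(p.parameter, 4), p.n_motus) for p in partitions])
abgd_best = choose_abgd_partition(partitions)
print("ABGD modal partition:", match_partition(abgd_best, taxonomy))

asap_best = asap_partition(matrix)[0]
print("ASAP top partition:  ", match_partition(asap_best, taxonomy))
print(
    "\nrate is the percentage of morphological species recovered exactly "
    "(all its samples in one MOTU, and nothing else in that MOTU)."
)
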