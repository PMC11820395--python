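"""Replicate reproducibility: intrabatch vs interbatch median %RSD.

Simulates the reproducibility design (six technical replicates per region,
each injected into five MS batches), processes the matrix, and reports the
median percent relative standard deviation per region: across replicates
within each batch (intrabatch) and across each replicate's repeat
injections (interbatch).
"""

from sebumetrics import (
    CohortConfig,
    build_feature_matrix,
    replicate_rsd_summaries,
    simulate_replicate_study,
)

sim = simulate_replicate_study(CohortConfig(rng_seed=0))
raw = build_feature_matrix(sim.spectra, sim.metadata)
summaries = replicate_rsd_summaries(raw, sim.metadata, n_keep=400)

print(f"{len(sim.spectra)} spectra: 6 replicates x 5 batches x 3 regions")
print("median %RSD (smaller = more reproducible):")
for region in ("forehead", "cheek", "neck"):
    intra = summaries["intrabatch"][region].median_percent_rsd
    inter = summaries["interbatch"][region].median_percent_rsd
    print(f"  {region:9s} intrabatch {intra:4.2f}%   interbatch {inter:4.2f}%")
print("intrabatch tracks the ~3% injected technical noise; interbatch adds")
print("the ~4% per-peak batch drift, so it is systematically larger.")
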