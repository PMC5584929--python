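"""Generate a synthetic phage metatranscriptome with known ground truth.

Builds the default study design: 33 lake samples, a 184-gene phage genome
plus a host genome with rpoB, negative-binomial read-pair counts whose
lysogeny / packaging-lysis / replication-structural blocks flip with the
latent infection state, and an environmental table linked to that state.
"""

import phagestate as ps

cfg = ps.SimConfig(seed=1)
models, truth, counts = ps.simulate_dataset(cfg)

print(f"genomes: {models.genome_ids}")
print(f"genes: {len(models)} (phage {sum(1 for g in models if g.genome_id == ps.simulate.PHAGE_GENOME)}, "
      f"host {sum(1 for g in models if g.genome_id == ps.simulate.HOST_GENOME)})")
print(f"samples: {len(counts.samples)}, library sizes "
      f"{int(counts.library_size.min())}-{int(counts.library_size.max())} pairs")
print("\nplanted states:")
print(truth.state_per_sample.value_counts().to_string())
print("\nfirst rows of the count matrix:")
print(counts.counts.iloc[:5, :4])
# The planted state per sample and the expected mean of every count are
# kept in `truth`, so downstream stages can be scored against the truth.
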