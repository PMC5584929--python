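# phagestate

Infers the infection program of a temperate cyanophage — **lytic
replication vs lysogeny** — from community RNA-seq of *Microcystis*
blooms, and relates it to water chemistry. The package is a tested,
reusable re-implementation of the full analysis chain: filtered
competitive read counting over phage/host gene models, marker-ratio
state classification, whole-genome co-expression clustering with
collapse of indistinguishable branches, and Bray-Curtis / nMDS / BIOENV
environmental-driver selection — together with a synthetic-data
generator with known ground truth so every stage is testable without any
download.

It is written for microbial ecologists and bioinformaticians who have
paired-end metatranscriptome alignments (SAM) against a phage genome
(Ma-LMM01-like, with markers *gp091*, *gp135*, *gp136*) and a host
genome carrying *rpoB*, or a precomputed gene × sample count table, plus
a per-sample environmental table.

## The statistic at the core

For each sample, expression of the lytic marker (viral tail sheath,
*gp091*) is compared with the primary lysogeny marker (IS607 transposase,
*gp135*) on rpoB-normalized counts:

    log2 ratio = log2( e(gp091) / e(gp135) )

ratio > 0 → lytic-dominated, ratio < 0 → lysogenic-dominated. Around it:
read pairs are counted within ORFs after 0.9 length-fraction and 0.9
identity-fraction filters with cross-genome pairs excluded; gene–gene
association uses Pearson ρ (p ≤ 0.1 edges) with average-linkage
clustering on 1 − ρ and a SIMPROF-style permutation collapse; sample
resemblance is Bray-Curtis on √(counts per million), embedded by
non-metric MDS (Kruskal stress-1); the BEST/BIOENV search maximizes
Spearman ρ between Euclidean environmental-subset distances and the
expression resemblance.

## Worked example

```python
import phagestate as ps

cfg = ps.SimConfig(n_samples=35, n_dead_samples=2,
                   library_size_range=(200_000, 200_000), seed=3)
models, truth, counts = ps.simulate_dataset(cfg)
phage = [g.gene_id for g in models if g.genome_id == ps.simulate.PHAGE_GENOME]

excluded = ps.flag_negligible(counts, phage, "rpoB", min_total_pairs=10)
kept = counts.drop_samples(list(excluded))
calls = ps.classify_state(ps.rpob_normalize(kept), excluded=excluded)
print(calls["state"].value_counts())
for r in ps.marker_correlations(ps.log2_shift_matrix(kept)):
    print(r.gene_a, r.gene_b, f"rho={r.rho:+.2f}", f"p={r.p_value:.2g}")
```

prints (seed 3):

```
lysogenic    20
lytic        13
excluded      2
gp091 gp135 rho=-0.37 p=0.035
gp091 gp136 rho=-0.36 p=0.04
gp135 gp136 rho=+0.92 p=1.4e-14
```

Two planted-dead libraries are excluded by the negligible-expression
rule; the remaining 33 samples are called by the sign of the marker
ratio (accuracy 1.00 against the planted truth here); the lytic marker
anticorrelates with both lysogeny markers while the transposase and
recombinase are tightly co-expressed — the signature of a community
switching between the two programs.

The `examples/` directory holds one short script per capability
(simulation, SAM round-trip quantification, state calls, co-expression
collapse, ordination + BEST), each printing the numbers it computes and
a line on what they mean. A thin CLI mirrors the stages:

```bash
phagestate simulate --out sim --seed 1
phagestate classify --counts sim/counts.tsv --out calls.tsv
phagestate quantify --sam s1.sam --sam s2.sam --genes models.gff3 --out counts.tsv
```

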