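# Methods

`phagestate` infers the infection program of a temperate cyanophage —
lytic replication versus lysogeny — from community RNA-seq, following the
analysis style used for *Microcystis aeruginosa* blooms and the
Ma-LMM01-like myovirus. This note documents the models, the numeric
choices, and what the synthetic benchmark does and does not demonstrate.

## The inference problem

A temperate phage transcribes different gene sets in its two programs:
structural and replication genes (tail sheath *gp091*, tail tube
*gp088*/*gp092*, head proteins *gp086*/*gp087*, lysozymes, terminase)
during lytic infection, and integration machinery (the IS607 transposase
*gp135* and serine recombinase *gp136*, plus *gp031*/*gp032*/*gp171*/
*gp067*) during lysogeny. Bulk metatranscriptomes therefore carry a
per-sample signature of which program dominates the phage population,
even though no single infected cell is observed.

## Read quantification

Input is one SAM file of paired-end alignments per sample, produced by
competitive mapping against the phage genome and a host genome carrying
*rpoB*. The counting contract is:

- **Mate filters.** A mate survives iff `aligned_length / read_length >=
  0.9` and `(aligned_length - mismatches) / aligned_length >= 0.9`.
  Identity is computed over the aligned segment, not the whole read,
  because the two cutoffs are independent. Mismatches come from the NM
  tag (minus indel bases) with an MD-tag fallback; records with neither,
  or with hard clips covering more than half the read, are rejected as
  malformed.
- **Competitive resolution.** If a mate has several candidate alignments,
  the single best by `aligned_length - mismatches` wins. Ties are broken
  uniformly with a seeded generator (`random_best`, the default, matching
  the behavior of common read mappers) or discarded (`discard_ties`, the
  conservative option).
- **Pair screen.** A pair is retained only if both mates resolved, both
  pass the filters, and both map to the same genome. Cross-genome pairs
  are excluded outright and tallied, as are orphans and filter failures
  (the audit TSV records every exclusion reason).
- **ORF counting.** A retained pair increments one gene when it satisfies
  the containment rule; the default `both_within` requires both mates
  fully inside the ORF (the literal reading of counting pairs "within"
  ORFs). `fragment_within` and `any_overlap` are config options because
  the boundary behavior is a genuine modeling choice. Pairs hitting no
  ORF go to an intergenic tally, so per sample `sum(gene counts) +
  intergenic = retained pairs` holds exactly. Gene models must be
  disjoint within a genome; overlapping models are rejected rather than
  double-counted. Coordinates are 0-based half-open internally; GFF3 is
  converted at the boundary.

## Normalizations

All transforms return a matrix tagged with its transform chain, so any
value is reproducible from raw counts.

- `libsize_normalize`: counts per million retained pairs (the scale
  factor is cosmetic — it cancels in ratios and in Bray-Curtis).
- `rpob_normalize`: division by the sample's *rpoB* count, a host-cell-
  density proxy; samples with zero *rpoB* are dropped with a logged
  reason rather than pseudocounted, consistent with the negligible-
  expression exclusion below.
- `log2_shift`: log2(x + 10), the transform used before Pearson
  correlation of marker abundances.
- `sqrt_transform`: the variance-stabilizer applied before Bray-Curtis.

All are elementwise monotone, so within-sample ranks are preserved.

## State classification

Samples with negligible data are excluded first: total phage pairs below
`min_total_pairs` (default 10 — the smallest count at which a marker
ratio has any resolution) or zero *rpoB*. Each remaining sample gets

    log2_ratio = log2((e_gp091 + eps) / (e_gp135 + eps))

on rpoB-normalized expression, with `eps` = half the smallest nonzero
value in the matrix so zero-vs-zero resolves to exactly 0 and expressed
markers are essentially unaffected. Ratio > 0 (outside an optional
`tie_band`) is called lytic-dominated, < 0 lysogenic-dominated. The
*gp136* ratio is available as a secondary check, and the classification
is antisymmetric under swapping marker roles. Marker cross-correlations
(Pearson on log2(x+10) abundance) use the classical t reference with
n − 2 df; a seeded permutation test (B = 9999) is available for small n.

## Co-expression clustering and branch collapse

Gene association is Pearson rho across samples (zero-variance genes
dropped and logged), with distance d = 1 − rho and two-sided t-based
p-values; the p ≤ 0.1 cutoff defines "significantly co-expressed" edges
in cluster reports. Clustering is agglomerative (average linkage by
default, complete available) with genes sorted lexicographically first so
the merge structure is input-order independent.

Branches whose members are statistically indistinguishable are collapsed
by a similarity-profile (SIMPROF-style) permutation test, applied
top-down: the node statistic is the *dispersion* of its correlation
profile, pi = mean |pairwise rho − mean pairwise rho|. A homogeneous node
— genes sharing one expression program plus exchangeable noise, or pure
noise — has a flat profile whose dispersion matches what independent
within-gene permutation of sample values produces; a node mixing distinct
programs has both high and low pairwise correlations and a dispersed
profile. Homogeneity is the null: if p ≤ alpha (default 0.05, B = 999,
seeded) the node is split and its children tested; otherwise it becomes
one collapsed group and its descendants are not tested, so the collapsed
groups partition the genes. The dispersion statistic rather than raw mean
correlation is essential: a clique of strongly but *uniformly*
co-expressed genes is exactly the case that should collapse. Under a
global null the root collapses in ~1 − alpha of datasets; alpha = 0
collapses everything into the root and alpha = 1 splits to singletons.

## Ordination and environmental drivers

- **Bray-Curtis** on square-root-transformed, library-size-normalized
  expression: d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j) ∈ [0, 1]; an all-zero
  sample pair is defined as distance 0 with a warning.
- **Non-metric MDS** minimizes Kruskal stress-1 by alternating isotonic
  regression of configuration distances on the dissimilarities with a
  Guttman (SMACOF) update. Iteration stops as soon as stress fails to
  decrease (the previous configuration is kept), so the recorded stress
  trace is non-increasing by construction; convergence tolerance 1e-7,
  max 300 iterations. The first restart starts from the classical
  metric-scaling solution and the remaining restarts (default 50) from
  seeded random configurations; the lowest-stress restart is returned,
  centered and principal-axis rotated with a deterministic sign
  convention so runs are comparable. Exactly embeddable inputs (points
  that truly live in 2-D, or any 3-sample metric) reach stress ~0.
- **envfit**: each environmental variable is regressed on the 2-D
  coordinates; the vector direction is the least-squares coefficient
  direction, its length the multiple correlation R, and its p-value comes
  from permuting the variable across samples (one shared, seeded
  permutation set for all variables, making p-values column-order
  invariant and sign-equivariant).
- **BEST (BIOENV)**: variables are z-scored; for every non-empty subset
  up to `max_subset_size` (exhaustive — at ≤ 20 candidates this is fully
  enumerable and is its own oracle, so no stepwise heuristic is used) the
  Euclidean distances over the subset are rank-correlated (Spearman,
  average ranks for ties) with the expression resemblance. The square
  root of the subset distance is omitted since ranks are invariant to it.
  Reported: the global best subset, per-size bests, and a global
  permutation p from re-running the entire search on sample-permuted
  environmental tables (B = 99 by default; 0 skips it). Missing values
  are refused, never silently pairwise-deleted.
- **Similarity contours** are reduced to tables: average-linkage
  membership at 40/60/80% similarity cuts of the same resemblance matrix.

## The synthetic-data generator

The generator is the test harness's ground truth and emulates the study
design the pipeline targets; its defaults are the study conditions.

- **Design**: 33 samples named by month (June–October) and station
  (1–11); 184 phage genes laid out as disjoint ORFs (300–1500 bp,
  20–200 bp gaps) always containing the named markers; a host genome with
  *rpoB* (3.6 kb, five-fold housekeeping boost) plus four background host
  genes; library sizes uniform on 1e5–1e6 read pairs; 125 bp paired
  reads.
- **Environment and state**: the 18 limnological variables (temperature,
  conductivity, total dissolved solids, salinity, pH, turbidity,
  chlorophyll, phycocyanin, dissolved oxygen, Secchi depth, water depth,
  and the N/P nutrient series) are multivariate normal with exchangeable
  correlation 0.3 — correlated candidates force BEST to discriminate, as
  in real tables. P(lysogenic | env) is logistic in the z-scored
  variables; the default coefficients pull toward lysogeny with pH and
  total dissolved phosphorus and toward the lytic state with total
  dissolved solids, dissolved nitrogen and oxygen.
- **Counts**: count(g, s) ~ NB with mean libsize(s) × baseline(g) ×
  fold(block(g), state(s)) and var = μ + αμ², α = `dispersion` (default
  0.3, the RNA-seq convention). Baselines are log-normal (σ = 1) for a
  realistic dynamic range; the three focal markers share one baseline
  draw because the ratio classifier's decision boundary at log2 ratio = 0
  presumes the markers flip *dominance*, not absolute scale. The lysogeny
  block is up-regulated `state_fold_change`-fold (default 10) in
  lysogenic samples; the packaging/lysis and replication/structural
  blocks in lytic samples; host genes are state-independent. Per-sample
  means are renormalized to the drawn library size (fixed sequencing
  depth). Because the two lytic blocks share one mean response, they are
  statistically one co-expression cluster in generator output; planted
  three-block *correlation* structure for cluster-recovery tests is built
  directly (shared factor + noise at within-block rho 0.8).
- **Read emission**: every counted pair becomes a proper SAM pair with
  both mates inside its source ORF, NM tags from binomial substitutions
  at `seq_error_rate` (default 0.005/base), and an optional fraction of
  decoy pairs (cross-genome, low-identity NM = 14, short-alignment
  100M25S) each carrying its truth label in the `ZT` tag so filter
  accounting is exact without side files.
- **Determinism**: every operation draws from its own named stream of the
  configured seed; identical config + seed gives byte-identical outputs.
- `n_dead_samples` plants libraries of size zero to exercise the
  negligible-expression exclusion (the 35 → 33 usable-samples situation).

**What passing tests do not show.** The generator has no rRNA carryover,
no positional or GC bias, no per-cycle quality structure, no strain-level
sequence variation and no compositional coupling beyond the fixed-depth
renormalization; no published count-noise model exists for these data, so
the negative binomial with fixed dispersion is a declared stand-in.
Recovery rates measured here are therefore upper bounds on real-data
performance, and the filter-accounting and round-trip results validate
the *counting logic*, not any aligner.

## Problem sizes used by tests and the acceptance script

Round-trip and filter checks run at 1–4 samples × 15–25 genes × a few
thousand pairs (SAM emission at full library scale would be gigabytes of
text for no additional coverage). Statistical checks run at the study
scale of n = 33 samples: 10–20 seeds for state recovery, 2000 null pairs
and 500 planted-correlation replicates, 150 genes × 3 blocks for cluster
recovery, and 10–25 seeded runs of the full ordination + BEST chain
(restarts 8–20, BEST subsets up to size 4–5, permutation p off in the
repeated-run rate estimates).

## Known limitations

- Pearson sampling error at n = 33 is irreducible: the standard deviation
  of an estimated rho near ±0.6 is ≈ 0.11, so roughly a fifth of
  replicates fall outside ±0.15 of truth regardless of implementation.
- The marker-ratio call is a dominance statement about the phage
  *population* in a sample, not evidence of integration in any cell;
  indeterminate calls occur only on exact ties (probability ~0 on
  continuous data with `tie_band` 0).
- nMDS is invariant to monotone transformations of the input
  dissimilarities, so configurations are comparable only up to rotation,
  reflection and scale; principal-axis rotation fixes this for testing
  but axis signs carry no meaning.
- BEST's global permutation p is conditional on the searched subset
  family; with correlated candidate variables the selected subset is not
  unique, and membership of a variable should be read as "carries
  signal", not "is the driver".
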