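"""Synthetic metatranscriptome generator with known ground truth.

Emulates the study design this pipeline targets: ~33 usable lake samples,
paired-end 125 bp libraries of 1e5-1e6 read pairs competitively mapped to
one ~184-gene phage genome (Ma-LMM01-like) and one host genome carrying
rpoB, with phage genes falling into three co-expression blocks whose
dominance flips between a latent lytic and a latent lysogenic state, and
with the latent state linked to water-chemistry covariates through a
logistic model.

Counts follow a negative-binomial model in the RNA-seq convention
var = mu + dispersion * mu^2. The generator is a stand-in for real
libraries (no published count-noise model exists for these data); see
docs/methods.md for what it does and does not emulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import CountMatrix
from .genes import GeneModel, GeneModelSet

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


#: Environmental variables of a standard limnological sampling table,
#: with plausible summer-bloom means and standard deviations (units:
#: degC, uS/cm, mg/L, PSU, pH units, NTU, ug/L, ug/L, mg/L, m, m,
#: mg/L x7, ug/L).
ENV_VARIABLES: dict[str, tuple[float, float]] = {
    "WaterTem": (28.0, 3.0),
    "EC": (550.0, 80.0),
    "TDS": (420.0, 60.0),
    "Sal": (0.25, 0.05),
    "pH": (8.5, 0.4),
    "NTU": (45.0, 20.0),
    "YSI_CHL": (30.0, 15.0),
    "PC": (60.0, 30.0),
    "DO": (8.5, 1.5),
    "SD": (0.4, 0.15),
    "WaterDep": (2.5, 0.5),
    "TN": (3.5, 1.5),
    "TDN": (2.0, 0.8),
    "NH4": (0.5, 0.3),
    "TP": (0.2, 0.1),
    "TDP": (0.08, 0.04),
    "PO4": (0.03, 0.02),
    "CHLa": (40.0, 25.0),
}

PHAGE_GENOME = "phage_MaLMM01like"
HOST_GENOME = "host_Microcystis"
RPOB = "rpoB"

#: Canonical phage genes with fixed co-expression block membership.
CANONICAL_BLOCKS: dict[str, str] = {
    "gp031": "lysogeny",
    "gp032": "lysogeny",
    "gp067": "lysogeny",
    "gp135": "lysogeny",
    "gp136": "lysogeny",
    "gp171": "lysogeny",
    "gp069": "packaging_lysis",
    "gp095": "packaging_lysis",
    "gp118": "packaging_lysis",
    "gp128": "packaging_lysis",
    "gp134": "packaging_lysis",
    "gp086": "replication_structural",
    "gp087": "replication_structural",
    "gp088": "replication_structural",
    "gp091": "replication_structural",
    "gp092": "replication_structural",
}

CORE_MARKERS = ("gp091", "gp135", "gp136")

#: Fraction of phage genes in the packaging/lysis block (60 of 184 in the
#: reference genome); the lysogeny block keeps only its canonical members
#: and the replication/structural block absorbs the remainder.
_PACKAGING_FRACTION = 60 / 184


def _default_env_coefficients() -> dict[str, float]:
    # Positive pushes toward lysogeny, negative toward the lytic state.
    return {
        "pH": 1.5,
        "TDS": -1.5,
        "TDN": -1.0,
        "TDP": 1.0,
        "DO": -0.5,
        "WaterTem": 0.5,
    }


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_samples: int = 33
    n_phage_genes: int = 184
    n_host_genes: int = 5
    library_size_range: tuple[int, int] = (100_000, 1_000_000)
    dispersion: float = 0.3
    state_fold_change: float = 10.0
    env_state_coefficients: dict[str, float] = field(
        default_factory=_default_env_coefficients
    )
    env_intercept: float = 0.0
    env_correlation: float = 0.3
    baseline_sigma: float = 1.0
    read_length: int = 125
    seq_error_rate: float = 0.005
    n_dead_samples: int = 0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_phage_genes < 1 or self.n_host_genes < 1:
            raise ConfigError("all counts must be positive")
        if self.n_phage_genes < 10:
            raise ConfigError(
                "n_phage_genes too small to place all named marker genes (need >= 10)"
            )
        if self.library_size_range[0] < 1 or (
            self.library_size_range[1] < self.library_size_range[0]
        ):
            raise ConfigError("library_size_range must be a positive, ordered pair")
        if not self.dispersion > 0:
            raise ConfigError("dispersion must be > 0")
        if not self.state_fold_change >= 1:
            raise ConfigError("state_fold_change must be >= 1")
        if not (0.0 <= self.seq_error_rate <= 0.1):
            raise ConfigError("seq_error_rate must lie in [0, 0.1]")
        if self.read_length < 1:
            raise ConfigError("read_length must be positive")
        if self.n_dead_samples < 0 or self.n_dead_samples >= self.n_samples:
            raise ConfigError("n_dead_samples must be in [0, n_samples)")
        unknown = set(self.env_state_coefficients) - set(ENV_VARIABLES)
        if unknown:
            raise ConfigError(f"unknown environmental variables: {sorted(unknown)}")
        coef = np.array(list(self.env_state_coefficients.values()), dtype=float)
        if coef.size and not np.all(np.isfinite(coef)):
            raise ConfigError("env_state_coefficients must be finite")
        if not np.isfinite(self.env_intercept):
            raise ConfigError("env_intercept must be finite")

    def coefficient_vector(self) -> np.ndarray:
        """Coefficients as a dense vector over ENV_VARIABLES order."""
        return np.array(
            [self.env_state_coefficients.get(v, 0.0) for v in ENV_VARIABLES]
        )

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named randomness stream."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class SimTruth:
    """Ground truth recorded while generating a synthetic dataset."""

    state_per_sample: pd.Series
    env_table: pd.DataFrame
    p_lysogenic: pd.Series
    metadata: pd.DataFrame
    dead_samples: list[str] = field(default_factory=list)
    block_of_gene: Optional[pd.Series] = None
    expected_mean_matrix: Optional[pd.DataFrame] = None

    @property
    def samples(self) -> pd.Index:
        return self.state_per_sample.index


def sample_names(n_samples: int) -> tuple[list[str], pd.DataFrame]:
    """Monthly station labels T{month}_{station} spread over 11 stations
    and the June-October bloom season."""
    pairs = [(m, s) for s in range(1, 12) for m in range(6, 11)]
    reps = -(-n_samples // len(pairs))  # ceil
    pairs = pairs * reps
    idx = np.round(np.linspace(0, len(pairs) - 1, n_samples)).astype(int)
    chosen = [pairs[i] for i in idx]
    names, stations, months = [], [], []
    seen: dict[str, int] = {}
    for m, s in chosen:
        name = f"T{m:02d}_{s}"
        if name in seen:
            seen[name] += 1
            name = f"{name}r{seen[name]}"
        else:
            seen[name] = 0
        names.append(name)
        stations.append(s)
        months.append(m)
    meta = pd.DataFrame({"station": stations, "month": months}, index=names)
    return names, meta


def _phage_gene_names(n: int) -> list[str]:
    if n >= 171:
        names = [f"gp{i:03d}" for i in range(1, n + 1)]
    else:
        named = sorted(CANONICAL_BLOCKS) if n >= len(CANONICAL_BLOCKS) else list(
            CORE_MARKERS
        )
        fillers = [f"gp{i:03d}" for i in range(1, 1000) if f"gp{i:03d}" not in named]
        names = sorted(named + fillers[: n - len(named)])
    return names


def _assign_blocks(names: Sequence[str], rng: np.random.Generator) -> dict[str, str]:
    blocks = {g: CANONICAL_BLOCKS[g] for g in names if g in CANONICAL_BLOCKS}
    rest = [g for g in names if g not in CANONICAL_BLOCKS]
    rng.shuffle(rest)
    target_packaging = max(
        0, int(round(_PACKAGING_FRACTION * len(names)))
        - sum(1 for b in blocks.values() if b == "packaging_lysis")
    )
    for i, g in enumerate(rest):
        blocks[g] = "packaging_lysis" if i < target_packaging else "replication_structural"
    return blocks


def make_genome_models(config: SimConfig) -> GeneModelSet:
    """Lay out non-overlapping ORFs for one phage and one host genome.

    Gene lengths are uniform on [300, 1500) bp with 20-200 bp intergenic
    gaps; the phage genome always contains gp091, gp135 and gp136 (and all
    sixteen canonically named genes whenever it is large enough), the host
    genome always contains rpoB.
    """
    rng = config.rng(1)
    names = _phage_gene_names(config.n_phage_genes)
    blocks = _assign_blocks(names, config.rng(11))
    genes: list[GeneModel] = []
    pos = 0
    for name in names:
        length = int(rng.integers(300, 1500))
        genes.append(
            GeneModel(
                gene_id=name,
                genome_id=PHAGE_GENOME,
                start=pos,
                end=pos + length,
                strand="+" if rng.random() < 0.5 else "-",
                role=blocks[name],
            )
        )
        pos += length + int(rng.integers(20, 200))
    pos = 0
    host_names = [RPOB] + [f"host_g{i}" for i in range(1, config.n_host_genes)]
    for name in host_names:
        length = 3600 if name == RPOB else int(rng.integers(300, 1500))
        genes.append(
            GeneModel(
                gene_id=name,
                genome_id=HOST_GENOME,
                start=pos,
                end=pos + length,
                strand="+",
                role="host",
            )
        )
        pos += length + int(rng.integers(20, 200))
    return GeneModelSet(genes)


def simulate_env_and_states(config: SimConfig) -> SimTruth:
    """Draw the environmental table and the latent infection states.

    Environmental variables are multivariate normal with exchangeable
    correlation ``env_correlation``; P(lysogenic | env) follows a logistic
    model on the per-variable z-scores.
    """
    rng = config.rng(2)
    names, meta = sample_names(config.n_samples)
    vars_ = list(ENV_VARIABLES)
    p = len(vars_)
    corr = np.full((p, p), config.env_correlation)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((config.n_samples, p)) @ chol.T
    means = np.array([ENV_VARIABLES[v][0] for v in vars_])
    sds = np.array([ENV_VARIABLES[v][1] for v in vars_])
    env = pd.DataFrame(means + sds * z, index=names, columns=vars_)

    std = env.to_numpy().std(axis=0)
    std[std == 0] = 1.0
    zstd = (env.to_numpy() - env.to_numpy().mean(axis=0)) / std
    eta = config.env_intercept + zstd @ config.coefficient_vector()
    p_lys = expit(eta)
    states = np.where(rng.random(config.n_samples) < p_lys, "lysogenic", "lytic")

    dead: list[str] = []
    if config.n_dead_samples:
        dead = sorted(
            rng.choice(names, size=config.n_dead_samples, replace=False).tolist()
        )
    return SimTruth(
        state_per_sample=pd.Series(states, index=names, name="state"),
        env_table=env,
        p_lysogenic=pd.Series(p_lys, index=names, name="p_lysogenic"),
        metadata=meta,
        dead_samples=dead,
    )


def _fold_factor(block: str, state: str, fc: float) -> float:
    if block == "lysogeny":
        return fc if state == "lysogenic" else 1.0
    if block in ("packaging_lysis", "replication_structural"):
        return fc if state == "lytic" else 1.0
    return 1.0  # host genes are state-independent


def simulate_counts(
    truth: SimTruth, models: GeneModelSet, config: SimConfig
) -> CountMatrix:
    """Draw the gene x sample count matrix.

    count(g, s) ~ NB(mean = libsize(s) * baseline(g) * fold(block(g),
    state(s)), var = mean + dispersion * mean^2). Baselines are log-normal;
    the three core marker genes share one baseline draw so that the state
    flips their dominance rather than their absolute scale, and rpoB gets a
    five-fold housekeeping boost. Per-sample means are renormalized so the
    expected total equals the drawn library size (fixed sequencing depth).
    """
    rng = config.rng(3)
    genes = models.gene_ids
    samples = list(truth.samples)
    blocks = pd.Series({g.gene_id: g.role or "host" for g in models}, name="block")

    base = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=len(genes))
    base = pd.Series(base, index=genes)
    present_markers = [m for m in CORE_MARKERS if m in base.index]
    if present_markers:
        shared = float(np.exp(np.log(base[present_markers]).mean()))
        base[present_markers] = shared
    if RPOB in base.index:
        base[RPOB] *= 5.0

    lib = rng.integers(
        config.library_size_range[0],
        config.library_size_range[1] + 1,
        size=len(samples),
    ).astype(float)
    lib[[samples.index(s) for s in truth.dead_samples]] = 0.0

    fold = np.array(
        [
            [
                _fold_factor(blocks[g], truth.state_per_sample[s], config.state_fold_change)
                for s in samples
            ]
            for g in genes
        ]
    )
    mean = base.to_numpy()[:, None] * fold
    colsum = mean.sum(axis=0)
    mean = mean / colsum * lib[None, :]

    k = 1.0 / config.dispersion
    p = k / (k + mean)
    counts = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    counts[pos] = rng.negative_binomial(k, p[pos])

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth.block_of_gene = blocks.reindex(genes)
    truth.expected_mean_matrix = pd.DataFrame(mean, index=genes, columns=samples)
    return CountMatrix(
        counts=counts_df,
        library_size=counts_df.sum(axis=0),
        provenance={
            "generator": "negative_binomial",
            "dispersion": config.dispersion,
            "state_fold_change": config.state_fold_change,
            "target_library_size": {s: float(l) for s, l in zip(samples, lib)},
            "seed": config.seed,
        },
    )


DECOY_KINDS = ("cross_genome", "low_identity", "short_align")
#: SAM tag carrying the per-pair truth label ("ok" or a decoy kind).
TRUTH_TAG = "ZT"


def emit_read_fixtures(
    counts: CountMatrix,
    models: GeneModelSet,
    config: SimConfig,
    out_dir: str | Path,
    decoy_fraction: float = 0.0,
) -> dict[str, Path]:
    """Write one SAM file per sample realizing the counted pairs.

    Every counted pair becomes a properly paired record pair with both
    mates inside the source ORF and an NM tag reflecting injected
    substitutions. With ``decoy_fraction`` > 0, extra labeled decoy pairs
    (cross-genome, low-identity, short-alignment) are interleaved so the
    downstream filters can be audited exactly via the ZT tag.
    """
    import pysam

    if not (0.0 <= decoy_fraction < 1.0):
        raise ConfigError("decoy_fraction must lie in [0, 1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(4)
    rl = config.read_length

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": genome, "LN": models.genome_length(genome)}
            for genome in models.genome_ids
        ],
    }
    tid = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    usable = [g for g in models if g.length >= rl]
    skipped = [g.gene_id for g in models if g.length < rl]
    for gid in skipped:
        logger.warning("gene %s shorter than read length; skipped in emission", gid)
    phage_usable = [g for g in usable if g.genome_id == PHAGE_GENOME]
    host_usable = [g for g in usable if g.genome_id == HOST_GENOME]

    def write_pair(out, qname, g1, pos1, g2, pos2, nm1, nm2, cigar, proper, label):
        alen = sum(n for op, n in cigar if op == 0)
        for mate, (g, pos, nm) in enumerate(((g1, pos1, nm1), (g2, pos2, nm2))):
            a = pysam.AlignedSegment()
            a.query_name = qname
            a.query_sequence = "A" * rl
            a.query_qualities = pysam.qualitystring_to_array("I" * rl)
            a.reference_id = tid[g.genome_id]
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = cigar
            flag = 0x1 | (0x40 if mate == 0 else 0x80)
            if proper:
                flag |= 0x2
            flag |= 0x10 if mate == 1 else 0x20
            a.flag = flag
            other = (g2, pos2) if mate == 0 else (g1, pos1)
            a.next_reference_id = tid[other[0].genome_id]
            a.next_reference_start = other[1]
            if g1.genome_id == g2.genome_id:
                span = max(pos1, pos2) + alen - min(pos1, pos2)
                a.template_length = span if mate == 0 else -span
            a.set_tag("NM", int(nm))
            a.set_tag(TRUTH_TAG, label)
            out.write(a)

    paths: dict[str, Path] = {}
    full = [(0, rl)]
    for sample in counts.samples:
        path = out_dir / f"{sample}.sam"
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            n_true = 0
            for gene in usable:
                c = int(counts.counts.at[gene.gene_id, sample])
                if c == 0:
                    continue
                hi = min(gene.length, 2 * rl + 200)
                frags = rng.integers(rl, hi + 1, size=c)
                starts = gene.start + rng.integers(0, gene.length - frags + 1)
                nms = rng.binomial(rl, config.seq_error_rate, size=(c, 2))
                for i in range(c):
                    qname = f"{sample}.p{n_true}"
                    n_true += 1
                    write_pair(
                        out,
                        qname,
                        gene,
                        int(starts[i]),
                        gene,
                        int(starts[i] + frags[i] - rl),
                        nms[i, 0],
                        nms[i, 1],
                        full,
                        True,
                        "ok",
                    )
            if decoy_fraction > 0 and phage_usable and host_usable:
                n_decoy = rng.binomial(n_true, decoy_fraction / (1 - decoy_fraction))
                kinds = rng.integers(0, len(DECOY_KINDS), size=n_decoy)
                for j in range(n_decoy):
                    kind = DECOY_KINDS[kinds[j]]
                    qname = f"{sample}.d{j}"
                    g1 = phage_usable[int(rng.integers(len(phage_usable)))]
                    pos1 = int(rng.integers(g1.start, g1.end - rl + 1))
                    if kind == "cross_genome":
                        g2 = host_usable[int(rng.integers(len(host_usable)))]
                        pos2 = int(rng.integers(g2.start, g2.end - rl + 1))
                        write_pair(out, qname, g1, pos1, g2, pos2, 0, 0, full, False, kind)
                    elif kind == "low_identity":
                        nm = int(np.ceil(0.11 * rl))  # identity < 0.9
                        pos2 = min(pos1 + rl, g1.end - rl)
                        write_pair(out, qname, g1, pos1, g1, pos2, nm, nm, full, True, kind)
                    else:  # short_align
                        alen = int(0.8 * rl)  # length fraction < 0.9
                        cig = [(0, alen), (4, rl - alen)]
                        pos2 = min(pos1 + rl, g1.end - alen)
                        write_pair(out, qname, g1, pos1, g1, pos2, 0, 0, cig, True, kind)
        paths[sample] = path
    return paths


def simulate_dataset(
    config: SimConfig,
) -> tuple[GeneModelSet, SimTruth, CountMatrix]:
    """Convenience wrapper: genome models, truth and counts in one call."""
    models = make_genome_models(config)
    truth = simulate_env_and_states(config)
    counts = simulate_counts(truth, models, config)
    return models, truth, counts
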