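"""Competitive-mapping read quantification: SAM pairs -> gene counts.

Implements the counting contract used for the phage/host
metatranscriptome: per-mate alignment filters (length fraction >= 0.9 and
identity fraction >= 0.9 by default), competitive resolution of multi-hit
mates to the single best alignment, exclusion of pairs whose mates map to
different genomes, and enumeration of read pairs within ORFs.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .genes import GeneModel, GeneModelSet

TiePolicy = Literal["random_best", "discard_ties"]
Containment = Literal["both_within", "fragment_within", "any_overlap"]

_MD_MISMATCH = re.compile(r"(?<!\^)[ACGTN]")


class MalformedRecordError(ValueError):
    """Raised for alignment records that cannot be scored."""


@dataclass(frozen=True)
class AlignmentRecord:
    """The scored view of one aligned mate."""

    read_id: str
    mate: int
    genome_id: str
    start: int
    aligned_length: int
    read_length: int
    mismatches: int
    mapped: bool = True

    def __post_init__(self) -> None:
        if self.mapped:
            if self.aligned_length > self.read_length:
                raise MalformedRecordError(
                    f"{self.read_id}/{self.mate}: aligned_length > read_length"
                )
            if self.mismatches > self.aligned_length:
                raise MalformedRecordError(
                    f"{self.read_id}/{self.mate}: mismatches > aligned_length"
                )

    @property
    def end(self) -> int:
        return self.start + self.aligned_length

    @property
    def score(self) -> int:
        return self.aligned_length - self.mismatches


def passes_filters(
    rec: AlignmentRecord,
    min_length_fraction: float = 0.9,
    min_identity_fraction: float = 0.9,
) -> bool:
    """Mate-level filter: length fraction and identity fraction cutoffs.

    The identity fraction is computed over the aligned segment (not the
    full read), matching the two cutoffs being independent.
    """
    for f in (min_length_fraction, min_identity_fraction):
        if not (0 < f <= 1):
            raise ValueError("filter fractions must lie in (0, 1]")
    if rec.read_length == 0:
        raise MalformedRecordError(f"{rec.read_id}/{rec.mate}: zero read length")
    if not rec.mapped or rec.aligned_length == 0:
        return False
    if rec.aligned_length / rec.read_length < min_length_fraction:
        return False
    return (rec.aligned_length - rec.mismatches) / rec.aligned_length >= min_identity_fraction


def _best_candidates(candidates: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    mapped = [c for c in candidates if c.mapped]
    if not mapped:
        return []
    best = max(c.score for c in mapped)
    return [c for c in mapped if c.score == best]


def resolve_competitive(
    candidates: Sequence[AlignmentRecord],
    policy: TiePolicy = "random_best",
    rng: Optional[np.random.Generator] = None,
) -> Optional[AlignmentRecord]:
    """Pick the single best-scoring alignment of one mate, or nothing.

    Score is aligned_length - mismatches. Ties are broken uniformly at
    random under ``random_best`` (seeded generator required for
    reproducibility) and resolved to nothing under ``discard_ties``.
    """
    if candidates:
        ids = {(c.read_id, c.mate) for c in candidates}
        if len(ids) > 1:
            raise ValueError(f"candidates span multiple mates: {sorted(ids)}")
    best = _best_candidates(candidates)
    if not best:
        return None
    if len(best) == 1:
        return best[0]
    if policy == "discard_ties":
        return None
    if policy != "random_best":
        raise ValueError(f"unknown tie policy {policy!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    return best[int(rng.integers(len(best)))]


def pair_and_screen(
    m1: Optional[AlignmentRecord],
    m2: Optional[AlignmentRecord],
    min_length_fraction: float = 0.9,
    min_identity_fraction: float = 0.9,
) -> tuple[bool, str]:
    """Pair-level screen; returns (retained, reason).

    A pair survives only when both mates resolved, both pass the mate
    filters, and both map to the same genome; cross-genome pairs are
    excluded outright.
    """
    if m1 is None or m2 is None:
        return False, "orphan"
    if not (
        passes_filters(m1, min_length_fraction, min_identity_fraction)
        and passes_filters(m2, min_length_fraction, min_identity_fraction)
    ):
        return False, "filter_fail"
    if m1.genome_id != m2.genome_id:
        return False, "cross_genome"
    return True, "ok"


def _gene_for_pair(
    m1: AlignmentRecord,
    m2: AlignmentRecord,
    models: GeneModelSet,
    containment: Containment,
) -> Optional[GeneModel]:
    genome = m1.genome_id
    if containment == "both_within":
        g1 = models.locate(genome, m1.start)
        g2 = models.locate(genome, m2.start)
        if (
            g1 is not None
            and g1 is g2
            and m1.end <= g1.end
            and m2.end <= g1.end
        ):
            return g1
        return None
    frag_start = min(m1.start, m2.start)
    frag_end = max(m1.end, m2.end)
    if containment == "fragment_within":
        g = models.locate(genome, frag_start)
        if g is not None and frag_end <= g.end:
            return g
        return None
    if containment == "any_overlap":
        hits = models.overlapping(genome, frag_start, frag_end)
        if not hits:
            return None
        # at most one gene per pair: the largest overlap, lowest start on ties
        overlaps = [
            (min(frag_end, g.end) - max(frag_start, g.start), -g.start, g) for g in hits
        ]
        return max(overlaps, key=lambda t: (t[0], t[1]))[2]
    raise ValueError(f"unknown containment rule {containment!r}")


def count_pairs(
    pairs: Iterable[tuple[AlignmentRecord, AlignmentRecord]],
    models: GeneModelSet,
    containment: Containment = "both_within",
) -> tuple[pd.Series, int]:
    """Enumerate retained pairs within ORFs.

    A pair increments exactly one gene when it satisfies the containment
    rule for it (default: both mates fully inside the ORF); pairs hitting
    no ORF go to the returned intergenic tally. Gene models are disjoint,
    so a pair can never increment two genes.
    """
    counts = pd.Series(0, index=pd.Index(models.gene_ids, name="gene_id"), dtype=np.int64)
    intergenic = 0
    for m1, m2 in pairs:
        gene = _gene_for_pair(m1, m2, models, containment)
        if gene is None:
            intergenic += 1
        else:
            counts[gene.gene_id] += 1
    return counts, intergenic


def record_from_pysam(aln) -> Optional[AlignmentRecord]:
    """Convert a pysam AlignedSegment, or None for unusable records.

    NM is required for the mismatch count (MD fallback); indel bases in NM
    are discounted so mismatches reflect substitutions only. Records whose
    hard clips cover more than half the read are rejected as malformed.
    """
    if aln.is_unmapped or aln.cigartuples is None:
        return None
    aligned = sum(n for op, n in aln.cigartuples if op in (0, 7, 8))
    read_length = aln.infer_read_length() or 0
    hard = sum(n for op, n in aln.cigartuples if op == 5)
    if read_length and hard > 0.5 * read_length:
        raise MalformedRecordError(f"{aln.query_name}: hard clips cover >50% of read")
    if aln.has_tag("NM"):
        nm = int(aln.get_tag("NM"))
        indel = sum(n for op, n in aln.cigartuples if op in (1, 2))
        mism = max(0, nm - indel)
    elif aln.has_tag("MD"):
        mism = len(_MD_MISMATCH.findall(str(aln.get_tag("MD"))))
    else:
        raise MalformedRecordError(f"{aln.query_name}: neither NM nor MD tag present")
    return AlignmentRecord(
        read_id=aln.query_name,
        mate=2 if aln.is_read2 else 1,
        genome_id=aln.reference_name,
        start=aln.reference_start,
        aligned_length=min(aligned, read_length) if read_length else aligned,
        read_length=read_length or aligned,
        mismatches=mism,
    )


def quantify_sample(
    sam_path: str | Path,
    models: GeneModelSet,
    min_length_fraction: float = 0.9,
    min_identity_fraction: float = 0.9,
    tie_policy: TiePolicy = "random_best",
    containment: Containment = "both_within",
    seed: int = 0,
) -> tuple[pd.Series, int, Counter]:
    """Count retained pairs per gene for one SAM file.

    Returns (per-gene counts, library size = retained pairs, audit counter
    of exclusion reasons plus the intergenic tally).
    """
    import pysam

    rng = np.random.default_rng([seed, 0])
    by_read: dict[str, dict[int, list[AlignmentRecord]]] = {}
    audit: Counter = Counter()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for aln in fh:
            # secondary/supplementary hits join the candidate pool too
            try:
                rec = record_from_pysam(aln)
            except MalformedRecordError:
                audit["malformed"] += 1
                continue
            if rec is None:
                continue
            by_read.setdefault(rec.read_id, {1: [], 2: []})[rec.mate].append(rec)

    retained_pairs: list[tuple[AlignmentRecord, AlignmentRecord]] = []
    for read_id in by_read:
        cands = by_read[read_id]
        mates: list[Optional[AlignmentRecord]] = []
        for mate in (1, 2):
            cs = cands[mate]
            if len(_best_candidates(cs)) > 1 and tie_policy == "discard_ties":
                audit["tie_discarded"] += 1
            mates.append(resolve_competitive(cs, tie_policy, rng) if cs else None)
        ok, reason = pair_and_screen(
            mates[0], mates[1], min_length_fraction, min_identity_fraction
        )
        if not ok:
            audit[reason] += 1
            continue
        retained_pairs.append((mates[0], mates[1]))
    counts, intergenic = count_pairs(retained_pairs, models, containment)
    retained = len(retained_pairs)
    audit["retained"] = retained
    audit["intergenic"] = intergenic
    return counts, retained, audit


def quantify(
    sam_paths: Mapping[str, str | Path],
    models: GeneModelSet,
    min_length_fraction: float = 0.9,
    min_identity_fraction: float = 0.9,
    tie_policy: TiePolicy = "random_best",
    containment: Containment = "both_within",
    seed: int = 0,
) -> CountMatrix:
    """Quantify a set of per-sample SAM files into a CountMatrix."""
    cols, libs, audits, inter = {}, {}, {}, {}
    for i, (sample, path) in enumerate(sorted(sam_paths.items())):
        counts, retained, audit = quantify_sample(
            path,
            models,
            min_length_fraction,
            min_identity_fraction,
            tie_policy,
            containment,
            seed=seed + i,
        )
        cols[sample] = counts
        libs[sample] = retained
        inter[sample] = audit["intergenic"]
        audits[sample] = dict(audit)
    counts_df = pd.DataFrame(cols)
    return CountMatrix(
        counts=counts_df,
        library_size=pd.Series(libs),
        intergenic=pd.Series(inter),
        provenance={
            "min_length_fraction": min_length_fraction,
            "min_identity_fraction": min_identity_fraction,
            "tie_policy": tie_policy,
            "containment": containment,
            "seed": seed,
            "audit": audits,
        },
    )


def write_audit_tsv(counts: CountMatrix, path: str | Path) -> None:
    """Persist the per-sample exclusion-reason audit as TSV."""
    audits = counts.provenance.get("audit", {})
    pd.DataFrame(audits).fillna(0).astype(int).rename_axis("reason").to_csv(
        path, sep="\t"
    )
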