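"""Gene models: genomic intervals of ORFs on named genomes.

All coordinates are 0-based half-open internally. GFF3 (1-based closed) is
converted on read and write; BED is already 0-based half-open.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd


class GeneModelError(ValueError):
    """Raised for invalid or ambiguous gene model sets."""


@dataclass(frozen=True)
class GeneModel:
    """One ORF interval on a named genome.

    ``role`` is a free-form annotation slot used here for co-expression
    block membership ("lysogeny", "packaging_lysis", "replication_structural",
    "host") and marker identity.
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str = "+"
    role: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GeneModelError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneModelSet:
    """A validated collection of non-overlapping ORFs grouped by genome.

    Overlapping intervals within a genome are rejected: counting pairs
    "within the ORF of a gene" is only unambiguous on disjoint models.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GeneModelError(f"duplicate gene ids: {dup}")
        self._by_id = {g.gene_id: g for g in self.genes}
        self._by_genome: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_genome.setdefault(g.genome_id, []).append(g)
        self._index: dict[str, tuple[np.ndarray, np.ndarray, list[GeneModel]]] = {}
        for genome, gs in self._by_genome.items():
            gs.sort(key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                if b.start < a.end:
                    raise GeneModelError(
                        f"overlapping genes on {genome}: {a.gene_id} and {b.gene_id}"
                    )
            self._index[genome] = (
                np.array([g.start for g in gs]),
                np.array([g.end for g in gs]),
                gs,
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self._by_genome)

    def genes_of(self, genome_id: str) -> list[GeneModel]:
        return list(self._by_genome.get(genome_id, []))

    def genome_length(self, genome_id: str, margin: int = 100) -> int:
        """Smallest plausible genome length covering all its ORFs."""
        gs = self._by_genome.get(genome_id)
        if not gs:
            raise GeneModelError(f"unknown genome {genome_id!r}")
        return max(g.end for g in gs) + margin

    def locate(self, genome_id: str, pos: int) -> Optional[GeneModel]:
        """Gene whose interval contains ``pos``, or None (intergenic)."""
        idx = self._index.get(genome_id)
        if idx is None:
            return None
        starts, ends, gs = idx
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return gs[i]
        return None

    def overlapping(self, genome_id: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose intervals intersect [start, end)."""
        idx = self._index.get(genome_id)
        if idx is None:
            return []
        starts, ends, gs = idx
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return gs[lo:hi]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "genome_id": [g.genome_id for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "role": [g.role for g in self.genes],
            }
        )

    # ------------------------------------------------------------------ IO

    def write_gff3(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("##gff-version 3\n")
            for genome in self.genome_ids:
                fh.write(f"##sequence-region {genome} 1 {self.genome_length(genome)}\n")
            for g in sorted(self.genes, key=lambda g: (g.genome_id, g.start)):
                attrs = f"ID={g.gene_id}"
                if g.role:
                    attrs += f";block={g.role}"
                fh.write(
                    "\t".join(
                        [
                            g.genome_id,
                            "phagestate",
                            "gene",
                            str(g.start + 1),  # GFF3 is 1-based closed
                            str(g.end),
                            ".",
                            g.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )

    def write_bed(self, path: str | Path) -> None:
        rows = [
            (g.genome_id, g.start, g.end, g.gene_id, 0, g.strand)
            for g in sorted(self.genes, key=lambda g: (g.genome_id, g.start))
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_gff3(cls, path: str | Path) -> "GeneModelSet":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
        genes = []
        for feat in db.all_features():
            if feat.featuretype not in ("gene", "CDS"):
                continue
            gid = feat.attributes.get("ID", [feat.id])[0]
            role = feat.attributes.get("block", [None])[0]
            genes.append(
                GeneModel(
                    gene_id=gid,
                    genome_id=feat.seqid,
                    start=feat.start - 1,  # back to 0-based half-open
                    end=feat.end,
                    strand=feat.strand if feat.strand in ("+", "-") else "+",
                    role=role,
                )
            )
        return cls(genes)

    @classmethod
    def read_bed(cls, path: str | Path) -> "GeneModelSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        genes = []
        for _, row in df.iterrows():
            strand = row[5] if df.shape[1] > 5 else "+"
            genes.append(
                GeneModel(
                    gene_id=str(row[3]),
                    genome_id=str(row[0]),
                    start=int(row[1]),
                    end=int(row[2]),
                    strand=str(strand),
                )
            )
        return cls(genes)
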